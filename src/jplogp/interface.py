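"""File I/O, model bundles, reference libraries and synthetic data.

Formats
-------
* Structures: SMILES files (one molecule per line, optional tab-separated
  id) and SDF V2000.
* Coefficient tables: CSV ``code,coefficient`` preceded by a ``#``-prefixed
  metadata header that carries the typer version tag; loading refuses a
  table built with a different typer vocabulary.
* Libraries: CSV ``id,smiles,logp`` with holograms cached to a sidecar
  JSON keyed by typer version.

The module also owns the synthetic-data generators used for testing and
self-contained end-to-end runs: a fixed fixture panel of ~60 molecules
spanning every classifier family, a combinatorial scaffold×substituent
molecule library, and training-set builders with either toy linear targets
or Wildman–Crippen logP targets.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen

from .atom_typer import TYPER_VERSION, TyperError, perceive, type_molecule
from .predictor import LibraryEntry
from .trainer import CoefficientTable, TrainingRecord, TrainingSet

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")  # per-record failures are reported by us

#: Prediction-time defaults that a config file may override.
DEFAULT_CONFIG = {
    "min_similarity": 0.75,
    "max_matches": 5,
    "min_occurrence": 3,
}


class BundleVersionError(ValueError):
    """Coefficient table was built with an incompatible typer version."""


def load_config(path: str | Path | None) -> dict:
    """Merge an optional JSON config file over the built-in defaults."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            overrides = json.load(fh)
        unknown = set(overrides) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config.update(overrides)
    return config


# --------------------------------------------------------------------------
# Structure input
# --------------------------------------------------------------------------

def read_structures(
    path: str | Path, fmt: str | None = None
) -> list[tuple[str, Chem.Mol]]:
    """Read (id, molecule) records from a SMILES or SDF file.

    ``fmt`` is inferred from the extension when omitted (.sdf vs anything
    else = SMILES).  Records that fail to parse are logged and dropped;
    the function never raises on a bad record, only on an unreadable file.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() == ".sdf" else "smiles"
    if fmt == "sdf":
        return _read_sdf(path)
    if fmt == "smiles":
        return _read_smiles(path)
    raise ValueError(f"unknown structure format: {fmt}")


def _read_smiles(path: Path) -> list[tuple[str, Chem.Mol]]:
    records: list[tuple[str, Chem.Mol]] = []
    failures = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smiles, _, ident = line.partition("\t")
            ident = ident.strip() or f"line{lineno}"
            mol = Chem.MolFromSmiles(smiles.strip())
            if mol is None:
                failures += 1
                logger.warning("line %d: could not parse %r", lineno, smiles)
                continue
            records.append((ident, mol))
    if failures:
        logger.warning("%d of %d records failed to parse", failures, failures + len(records))
    return records


def _read_sdf(path: Path) -> list[tuple[str, Chem.Mol]]:
    records: list[tuple[str, Chem.Mol]] = []
    failures = 0
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            failures += 1
            logger.warning("SDF record %d failed to parse", i)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        records.append((name or f"record{i}", mol))
    if failures:
        logger.warning("%d of %d SDF records failed to parse", failures, len(supplier))
    return records


def write_smiles(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write (smiles, id) lines."""
    with open(path, "w") as fh:
        for smiles, ident in records:
            fh.write(f"{smiles}\t{ident}\n")


# --------------------------------------------------------------------------
# Model bundles (coefficient CSV with metadata header)
# --------------------------------------------------------------------------

def save_bundle(table: CoefficientTable, path: str | Path) -> None:
    """Write a coefficient table with its provenance header.

    Coefficients are serialised with ``repr`` so that a save/load cycle is
    bit exact.
    """
    with open(path, "w") as fh:
        fh.write("# jplogp coefficient table\n")
        for key in sorted(table.metadata):
            fh.write(f"# {key}: {table.metadata[key]}\n")
        fh.write("code,coefficient\n")
        for code in sorted(table.coefficients):
            fh.write(f"{code},{table.coefficients[code]!r}\n")


def load_bundle(path: str | Path, *, expect_version: str = TYPER_VERSION) -> CoefficientTable:
    """Load a coefficient table, refusing a typer-version mismatch."""
    metadata: dict = {}
    coefficients: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                key, sep, value = body.partition(":")
                if sep:
                    metadata[key.strip()] = _coerce(value.strip())
                continue
            if line.lower().startswith("code,"):
                continue
            code_s, _, coeff_s = line.partition(",")
            coefficients[int(code_s)] = float(coeff_s)
    version = metadata.get("typer_version")
    if version != expect_version:
        raise BundleVersionError(
            f"coefficient table was built with typer {version!r}, "
            f"but this package runs {expect_version!r}"
        )
    return CoefficientTable(coefficients=coefficients, metadata=metadata)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


# --------------------------------------------------------------------------
# Reference libraries
# --------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".holo.json")


def load_library(path: str | Path, *, use_cache: bool = True) -> list[LibraryEntry]:
    """Load a CSV library (id, smiles, logp) with experimental values.

    Holograms are computed on load and cached in a sidecar JSON keyed by
    the typer version; a stale or missing cache is rebuilt silently.
    Records that fail perception are logged and dropped.
    """
    path = Path(path)
    cache: dict[str, dict[int, int]] = {}
    sidecar = _sidecar_path(path)
    if use_cache and sidecar.exists():
        with open(sidecar) as fh:
            payload = json.load(fh)
        if payload.get("typer_version") == TYPER_VERSION:
            cache = {
                ident: {int(c): int(n) for c, n in h.items()}
                for ident, h in payload.get("holograms", {}).items()
            }

    entries: list[LibraryEntry] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ident, smiles, logp = row["id"], row["smiles"], float(row["logp"])
            h = cache.get(ident)
            if h is None:
                try:
                    h = type_molecule(perceive(smiles))
                except TyperError as exc:
                    logger.warning("library record %s dropped: %s", ident, exc)
                    continue
            entries.append(LibraryEntry(id=ident, structure=smiles, logp=logp, hologram=h))

    if use_cache:
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "typer_version": TYPER_VERSION,
                    "holograms": {
                        e.id: {str(c): n for c, n in sorted(e.hologram.items())}
                        for e in entries
                    },
                },
                fh,
            )
    return entries


def save_library(entries: list[LibraryEntry], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "logp"])
        for e in entries:
            writer.writerow([e.id, e.structure, e.logp])
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        sidecar.unlink()  # force rebuild so cache and CSV stay in step


def add_to_library(
    path: str | Path, new_records: list[tuple[str, str, float]]
) -> list[LibraryEntry]:
    """Append (id, smiles, logp) records to a library file and reload it."""
    path = Path(path)
    entries = load_library(path) if path.exists() else []
    known = {e.id for e in entries}
    for ident, smiles, logp in new_records:
        if ident in known:
            raise ValueError(f"library already contains id {ident!r}")
        try:
            h = type_molecule(perceive(smiles))
        except TyperError as exc:
            logger.warning("new library record %s dropped: %s", ident, exc)
            continue
        entries.append(LibraryEntry(id=ident, structure=smiles, logp=logp, hologram=h))
    save_library(entries, path)
    return load_library(path)


# --------------------------------------------------------------------------
# Synthetic data: fixture panel, combinatorial library, training sets
# --------------------------------------------------------------------------

#: Hand-picked panel spanning the classifier families: sp3/aromatic/
#: carbonyl/alkene/alkyne carbons; amine, aniline, amide, nitrile, nitro
#: and charged nitrogens; ether, hydroxyl, acid, ester, amide and
#: N/S-bound oxygens; all four halogens incl. polyfluorination; aromatic
#: and polar-substituted sulfur; phosphate; formally charged atoms.
FIXTURE_SMILES: tuple[tuple[str, str], ...] = (
    ("methane", "C"),
    ("ethane", "CC"),
    ("propane", "CCC"),
    ("isobutane", "CC(C)C"),
    ("cyclohexane", "C1CCCCC1"),
    ("ethanol", "CCO"),
    ("diethyl-ether", "CCOCC"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("pyridine", "c1ccncc1"),
    ("phenol", "Oc1ccccc1"),
    ("anisole", "COc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("thiophene", "c1ccsc1"),
    ("furan", "c1ccoc1"),
    ("pyrrole", "c1cc[nH]c1"),
    ("imidazole", "c1cnc[nH]1"),
    ("acetone", "CC(C)=O"),
    ("acetaldehyde", "CC=O"),
    ("benzaldehyde", "O=Cc1ccccc1"),
    ("acetic-acid", "CC(=O)O"),
    ("methyl-acetate", "COC(C)=O"),
    ("acetamide", "CC(N)=O"),
    ("n-methylacetamide", "CNC(C)=O"),
    ("benzamide", "NC(=O)c1ccccc1"),
    ("benzoic-acid", "OC(=O)c1ccccc1"),
    ("ethyl-benzoate", "CCOC(=O)c1ccccc1"),
    ("s-methyl-thioacetate", "CSC(C)=O"),
    ("urea", "NC(N)=O"),
    ("glycine", "NCC(=O)O"),
    ("morpholine", "C1COCCN1"),
    ("triethylamine", "CCN(CC)CC"),
    ("methylamine", "CN"),
    ("dimethylamine", "CNC"),
    ("piperidine", "C1CCNCC1"),
    ("hydrazine", "NN"),
    ("acetonitrile", "CC#N"),
    ("nitromethane", "C[N+](=O)[O-]"),
    ("nitrobenzene", "O=[N+]([O-])c1ccccc1"),
    ("fluorobenzene", "Fc1ccccc1"),
    ("chlorobenzene", "Clc1ccccc1"),
    ("bromobenzene", "Brc1ccccc1"),
    ("iodobenzene", "Ic1ccccc1"),
    ("4-chlorophenol", "Oc1ccc(Cl)cc1"),
    ("4-bromophenol", "Oc1ccc(Br)cc1"),
    ("chloroform", "ClC(Cl)Cl"),
    ("fluoroethane", "CCF"),
    ("trifluoromethylbenzene", "FC(F)(F)c1ccccc1"),
    ("1,1,1-trifluoroethane", "CC(F)(F)F"),
    ("dimethyl-sulfide", "CSC"),
    ("dimethyl-sulfoxide", "CS(C)=O"),
    ("methanethiol", "CS"),
    ("sulfanilamide", "NS(=O)(=O)c1ccc(N)cc1"),
    ("trimethyl-phosphate", "COP(=O)(OC)OC"),
    ("acetate-anion", "CC(=O)[O-]"),
    ("phenolate", "[O-]c1ccccc1"),
    ("tetramethylammonium", "C[N+](C)(C)C"),
    ("anilinium", "[NH3+]c1ccccc1"),
    ("ethylene", "C=C"),
    ("propene", "CC=C"),
    ("propyne", "CC#C"),
    ("styrene", "C=Cc1ccccc1"),
)


_SCAFFOLDS_1 = (
    "c1ccc({})cc1",
    "c1ccnc({})c1",
    "c1ccc({})cn1",
    "c1cc({})co1",
    "c1cc({})cs1",
    "C1CCC({})CC1",
    "c1ccc2cc({})ccc2c1",
    "Oc1ccc({})cc1",
    "CC{}",
    "CCCC{}",
    "CC(C){}",
)

_SCAFFOLDS_2 = (
    "c1cc({})ccc1{}",
    "C({})CC{}",
)

_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "I", "C#N", "[N+](=O)[O-]", "C(=O)O", "C(=O)OC",
    "C(=O)N", "C(=O)NC", "C(=O)C", "C=O", "S", "SC", "S(=O)(=O)N",
    "C(F)(F)F", "C=C", "C#C", "OC(=O)C",
)

_GENERATED_CACHE: list[str] | None = None


def generate_molecules() -> list[str]:
    """Deterministic combinatorial scaffold×substituent molecule library.

    Roughly 2,000 unique small organic molecules in canonical SMILES,
    sorted for reproducibility.  Invalid combinations are silently
    discarded during enumeration.
    """
    global _GENERATED_CACHE
    if _GENERATED_CACHE is not None:
        return list(_GENERATED_CACHE)
    seen: set[str] = set()
    for scaffold in _SCAFFOLDS_1:
        for sub in _SUBSTITUENTS:
            mol = Chem.MolFromSmiles(scaffold.format(sub))
            if mol is not None:
                seen.add(Chem.MolToSmiles(mol))
    for scaffold in _SCAFFOLDS_2:
        for sub_a in _SUBSTITUENTS:
            for sub_b in _SUBSTITUENTS:
                mol = Chem.MolFromSmiles(scaffold.format(sub_a, sub_b))
                if mol is not None:
                    seen.add(Chem.MolToSmiles(mol))
    _GENERATED_CACHE = sorted(seen)
    return list(_GENERATED_CACHE)


@dataclass
class FixtureSet:
    """Seed-deterministic labeled molecule panel for end-to-end tests."""

    records: list[TrainingRecord]
    smiles: dict[str, str]
    alpha_toy: dict[int, float]
    noise_sigma: float
    seed: int

    def training_set(self) -> TrainingSet:
        return TrainingSet(records=list(self.records))


def make_fixtures(seed: int, noise_sigma: float = 0.1) -> FixtureSet:
    """Build the fixture panel with synthetic linear targets.

    Each molecule's target is ``hologram · alpha_toy`` plus seeded
    Gaussian noise, where ``alpha_toy`` assigns every code in the panel's
    vocabulary a coefficient drawn from N(0, 0.4).  The construction is a
    ground-truth additive model, so training on the panel must recover the
    planted signal up to the noise level.
    """
    rng = np.random.default_rng(seed)
    typed: list[tuple[str, str, dict[int, int]]] = []
    for name, smiles in FIXTURE_SMILES:
        typed.append((name, smiles, type_molecule(perceive(smiles))))

    vocabulary = sorted({code for _, _, h in typed for code in h})
    alpha_toy = {code: float(rng.normal(0.0, 0.4)) for code in vocabulary}

    records = []
    for name, smiles, h in typed:
        clean = sum(alpha_toy[c] * n for c, n in h.items())
        target = clean + float(rng.normal(0.0, noise_sigma))
        records.append(TrainingRecord(id=name, hologram=h, target=target))
    return FixtureSet(
        records=records,
        smiles={name: smiles for name, smiles in FIXTURE_SMILES},
        alpha_toy=alpha_toy,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def crippen_logp(structure: str | Chem.Mol) -> float:
    """Wildman–Crippen atomic-contribution logP (RDKit), used as the
    locally available consensus-constituent predictor for training
    targets."""
    mol = structure if isinstance(structure, Chem.Mol) else Chem.MolFromSmiles(structure)
    if mol is None:
        raise TyperError(f"could not parse {structure!r}")
    return float(Crippen.MolLogP(mol))


def make_training_set(
    seed: int,
    n: int | None = None,
    noise_sigma: float = 0.0,
    include_panel: bool = True,
) -> TrainingSet:
    """Training set over the combinatorial molecule library.

    Targets are the consensus of the locally available constituent
    predictor (Wildman–Crippen logP), optionally perturbed by seeded
    Gaussian noise.  ``n`` subsamples the combinatorial library
    deterministically; by default every generated molecule is used.
    ``include_panel`` additionally folds in the hand-picked fixture panel,
    which contributes charged and other rare environments the
    combinatorial enumeration does not reach.
    """
    from .trainer import consensus_mean  # local import to avoid cycle noise

    rng = np.random.default_rng(seed)
    smiles_list = generate_molecules()
    if n is not None and n < len(smiles_list):
        idx = rng.choice(len(smiles_list), size=n, replace=False)
        smiles_list = [smiles_list[i] for i in sorted(idx)]
    if include_panel:
        known = set(smiles_list)
        for _, smiles in FIXTURE_SMILES:
            canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
            if canonical not in known:
                smiles_list.append(canonical)
                known.add(canonical)

    records = []
    skipped = 0
    for i, smiles in enumerate(smiles_list):
        try:
            h = type_molecule(perceive(smiles))
        except TyperError:
            skipped += 1
            continue
        target = consensus_mean([crippen_logp(smiles)])
        if noise_sigma:
            target += float(rng.normal(0.0, noise_sigma))
        records.append(TrainingRecord(id=f"gen{i:05d}", hologram=h, target=target))
    if skipped:
        logger.warning("%d generated molecules failed typing", skipped)
    return TrainingSet(records=records)
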