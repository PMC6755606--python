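# Methods

## Model

The predictor assumes logP is additive over atoms: each atom contributes
an amount determined solely by its *type*, a discrete code capturing
charge, element, steric crowding and local electronic environment. For a
molecule with hologram counts `Count_n` over atom types `n`,

    logP_coeff = Σ_n α_n · Count_n

with no intercept: the carbon and hydrogen types present in essentially
every molecule absorb the baseline, and adding an intercept would only
introduce a redundant direction into the design. The assumption shared
with all atomic/fragment contribution schemes is that long-range and
conformational effects are negligible or averaged out by the training set.

## Atom-type vocabulary

A code is `A|BB|C|DD` = `A·10⁵ + BB·10³ + C·10² + DD`: `A` = formal charge
+ 1 (charges below −1 are rejected as chemically implausible in organic
space; above +8 would overflow the digit), `BB` = atomic number (Z > 99 is
out of scope), `C` = heavy-neighbour count, `DD` = environment class.
"Polar atom" always means S, O, N or P. The `DD` numbering is a fixed
property of this package, stamped into every coefficient table as
`jplogp-typer/1.0`; tables from a different vocabulary are refused at
load time rather than silently mispriced.

| family | DD | class |
|---|---|---|
| carbon | 2 / 3 | sp3 without / with a polar neighbour |
| carbon | 10+4·m+s | aromatic, `m` polar via aromatic/multiple bond, `s` via single bond (each capped at 3) |
| carbon | 30+4·m+s | max bond order double, same subdivision |
| carbon | 50+4·m+s | max bond order triple, same subdivision |
| nitrogen | 1 | delocalised lone pair: single-bonded to an aromatic atom, or to a carbon double-bonded to O or S (aniline/amide/thioamide-like) |
| nitrogen | 2 | directly bound to a polar atom |
| nitrogen | 3/4/5/6 | otherwise by max bond order single/aromatic/double/triple |
| oxygen | 1 / 2 | bound to N / bound to S |
| oxygen | 3/4/5/6/7 | sp2 carbonyl O of amide / acid / ester / plain carbonyl / thio-acid-or-ester |
| oxygen | 8 / 9 / 0 | hydroxyl / ether (two heavy neighbours) / other |
| fluorine | 10·h+w | carrier carbon hybridisation h (1 sp3, 2 aromatic, 3 double, 4 triple), w additional withdrawing substituents (halogens + polar) on that carbon |
| fluorine | 0 | non-carbon carrier |
| hydrogen | 1/2/3/4 | carrier carbon by max bond order |
| hydrogen | 5 / 0 | carrier polar heavy atom / anything else |
| default | 50 | aromatic atom (any element without a bespoke family) |
| default | 0–9 | polar-neighbour count otherwise |

Design choices made where the design was genuinely open:

* **Bond-order ordering.** Maximum bond order ranks single < aromatic <
  double < triple, with aromatic its own group — an aromatic carbon is not
  an sp2 carbon for typing purposes, because the ring current and the
  localised π bond pull substituents differently.
* **Nitrogen precedence.** The delocalised-lone-pair test runs before the
  polar-bound test; a nitro nitrogen (O neighbours, no single bond to an
  aromatic atom or carbonyl carbon) therefore lands in the polar-bound
  class, an N-aryl-hydrazine in the delocalised class.
* **Carbamate-like oxygens.** An sp2 oxygen whose carbonyl carbon carries
  both N and O single-bonded neighbours is classed with the amides (N is
  checked first): the nitrogen's donation dominates the carbonyl's
  character.
* **Fluorine withdrawing count** excludes the fluorine being typed itself,
  so CH₃F counts zero and CF₄ counts three; this is what lets the model
  price fluorine's self-damping on polyfluorinated carbons.
* **Hydrogen classes** look exactly one bond away. Carbon carriers are
  split by max bond order, all polar heavy carriers share one class: finer
  carrier splits (O–H vs N–H) are already distinguished indirectly through
  the carrier's own code, and beta-position lookups would break the
  hologram's strict locality.
* **Default-family aromaticity** overrides the polar count (DD 50 is
  reserved), so an aromatic sulfur is always `…50` regardless of
  neighbours and never collides with a polar-count class.
* **Salts/mixtures**: the largest covalent fragment is kept with a
  warning; counter-ion-dominated chemistry is out of scope.

## Similarity and the library correction

Similarity between holograms is the count-generalised Tanimoto
`Σ min / Σ max` over the code union: symmetric, 1 exactly on identical
holograms, 0 on disjoint vocabularies, and identical to the classical
Tanimoto on presence/absence vectors. A per-position-mean variant
(average of min/max ratios) is available behind a keyword for comparison;
it is not the default because it over-weights rare codes relative to the
count mass. All codes participate, hydrogens included — hydrogen counts
carry real signal here (they respond to hybridisation and polarity of the
carrier), and excluding them would make dissimilar hydrogen-rich and
hydrogen-poor molecules look alike.

The library correction is exact linear algebra, not a heuristic: because
prediction is linear in the hologram,

    correct_from_known(u, k) − logP_coeff(u) = logP_exp(k) − logP_coeff(k)

to machine precision, so library mode replaces the model's estimate of the
*reference* with its measurement while keeping the model's estimate of the
*difference*. Matches are aggregated by unweighted mean (a
similarity-weighted mean is available but not default — no weighting
scheme is part of the method's definition); ties in similarity are broken
by library id so results are independent of library file order. A
reference whose difference hologram touches an untrained code is dropped
from the mean and reported, rather than poisoning the prediction. With no
qualifying match the coefficient prediction is returned, flagged
`mode="coeff"`. Defaults `min_similarity=0.75`, `max_matches=5`.

## Training

Targets may be consensus values — the arithmetic mean of several
predictors' outputs — or measurements; the trainer is agnostic. The design
matrix holds raw hologram counts (rows compounds, columns codes); codes
with fewer than 3 total atom-level occurrences across the set are dropped
before fitting (the threshold counts atoms, not compounds — a single
molecule with three fluorines of one type is deemed as informative as
three molecules with one each). The solver is SVD-based least squares
(`numpy.linalg.lstsq`): for a full-rank design it equals the QR solution;
for a rank-deficient design it returns the minimum-norm solution with a
warning. Rank deficiency is not an error condition for this model — codes
that always co-occur are genuinely unidentifiable individually, every
least-squares solution prices their sums identically, and predictions for
molecules in the training span are unaffected. Records that fail
perception are dropped and logged, never imputed. Refitting on the model's
own predictions reproduces the coefficients (tested), and the solution is
invariant to row and column order.

Fit statistics: R² = 1 − SS_res/SS_tot about the target mean, RMSE =
√(mean squared residual), both on the post-filter design.

## Targeted sampling

Given holograms for a large collection, the sampler walks codes in
ascending total-occurrence order and, for each code with at least
`min_occurrence` (default 3) occurrences, draws random compounds
containing it until `level` already-selected compounds contain it (or the
pool is exhausted). Compounds selected for rarer codes count toward later
quotas, keeping the subset compact. Compounds containing sub-threshold
codes are not excluded from the dataset — their rare codes are simply not
targeted (and will be filtered at training time). The guarantee, asserted
in tests: after sampling, every code with dataset occurrence ≥
`min_occurrence` appears in at least `min(level, pool size)` selected
compounds. Draws use a seeded generator recorded in the output manifest.

## Synthetic study conditions

The package carries no measured logP data, so its end-to-end conditions
are synthetic, in two tiers:

* **Fixture panel** (`make_fixtures`): ~60 hand-picked molecules spanning
  every classifier family (sp3/aromatic/carbonyl/alkene/alkyne carbons;
  amine, aniline, amide, nitrile, nitro and charged nitrogens; hydroxyl,
  ether, acid, ester, amide, N- and S-bound oxygens; all four halogens
  including polyfluorination; aromatic and polar-substituted sulfur;
  phosphate; anions and cations). Targets are a planted additive model
  `hologram · α_toy` + N(0, 0.1), with α_toy ~ N(0, 0.4) per code —
  magnitudes chosen to bracket the spread of typical per-atom logP
  contributions (roughly −1 to +1 log units). Because the ground truth is
  additive by construction, training must recover it; these fixtures test
  the machinery, not the chemistry.
* **Combinatorial library** (`generate_molecules`, ~2,000 molecules):
  benzene, pyridine, furan, thiophene, naphthalene, phenol, cyclohexane
  and alkane scaffolds crossed with 30 substituents (alkyl, hydroxy,
  alkoxy, amino, halo, nitro, nitrile, acid, ester, amide, thio,
  trifluoromethyl, alkenyl, alkynyl), singly and doubly substituted.
  Training targets are the consensus mean of the constituent predictors
  available locally — here the Wildman–Crippen atomic scheme, itself one
  of the standard consensus constituents — so the pipeline genuinely
  learns one additive model's view of another's chemistry. The acceptance
  run trains on ~1,000 of these (an 80/20 split of the ~1,234 total after
  deduplication and panel merge), a problem size chosen so a full
  from-scratch run completes in seconds while leaving the design strongly
  overdetermined (~20 rows per fitted coefficient).

What these conditions do **not** show: real experimental noise, tautomers,
zwitterions at physiological pH, conformation-dependent lipophilicity,
large natural products, or chemistry outside the enumerated scaffolds
(~60–70 atom types are exercised versus a few hundred in a production
training corpus). Passing tests demonstrate correctness of the typing,
algebra, fitting and selection logic — not field accuracy on pharmaceutical
space, which requires training on a large measured or consensus-predicted
corpus as described above.

## Numerical notes and degenerate inputs

* Similarity of two empty holograms is an error (undefined), not 0 or 1.
* Predicting from an empty hologram is an error; a hologram with codes
  missing from the table yields a value over the known codes plus an
  out-of-domain flag listing the missing codes.
* R² is an error on zero-variance targets.
* An underdetermined post-filter design (fewer compounds than codes) is an
  error; rank-deficient but overdetermined designs warn and proceed
  (minimum-norm).
* Coefficients serialise via `repr` so save→load round-trips are bit
  exact.
* Absolute-error bins for evaluation are half-open `[lo, hi)` at 0.5 steps
  with a final `[2, ∞)` bin, so every error lands in exactly one bin.

## Known limitations

* The DD vocabulary, while semantically faithful to the hierarchy
  described above, uses this package's own numbering; coefficient tables
  from other implementations of the same idea are not interchangeable
  (hence the hard version check at load time).
* No 3D perception, tautomer enumeration or pKa-based charge-state
  adjustment: the typed species is whatever the input SMILES/SDF encodes.
* Aromaticity follows RDKit's default model; a different aromaticity
  model shifts atoms between the aromatic and double-bond groups and would
  constitute a new typer version.
* The library correction assumes the reference's measurement and the
  query share conditions (temperature, ionisation state); no correction
  for measurement context is attempted.
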