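# Methods

This note records the scientific and numerical choices frozen into
`pyrimqsar`: the model, the descriptor conventions and how they were
fixed, the regression and validation statistics, the applicability
domain, and what the synthetic-data generator can and cannot stand in
for.

## 1. The model

The published five-descriptor multilinear model for HeLa pIC50 is

```
pIC50 = -4.66·AATSC2s - 1.99·MDEN-23 + 3.45·ATSC4c + 0.21·ATSC3e - 15.28·AATSC6p + 4.7326
```

with training statistics N = 31, k = 5, R² = 0.85, q²_LOO = 0.797,
F = 29.35, s² = 0.0485 and external R²_test = 0.64, and coefficient
t-values (−8.23321, −5.72486, 5.41163, 4.53965, −3.62229).
`pyrimqsar.model.published_model()` returns this instance with the
coefficients at their printed precision; nothing is ever re-fitted
there. The instance also pins the descriptor-computation configuration
(`DescriptorConfig`), because the numerical values of the five
descriptors depend on conventions the model name alone does not fix.

Activities convert as pIC50 = −log10(IC50 in mol/L) = 6 − log10(IC50 in
µM). Censored assay results ("> x µM") are carried as setpoints at x,
flagged as censored.

## 2. Descriptor definitions

### 2.1 Centered Broto–Moreau autocorrelations (ATSC / AATSC)

For a weighting scheme w with per-atom values w_i and mean w̄ over the
included atoms,

```
ATSC(k, w)  = Σ over unordered pairs {i, j} with d_ij = k of (w_i − w̄)(w_j − w̄)
AATSC(k, w) = ATSC(k, w) / Δ_k ,   Δ_k = number of pairs at distance k
```

with d_ij the shortest-path bond count. Both are 0 when Δ_k = 0.

### 2.2 Molecular distance-edge (MDEN)

Nitrogens are typed by heavy-atom degree (1 primary, 2 secondary —
including pyridine-type ring N, 3 tertiary). For types s ≤ t,

```
MDEN-st = n_st / GM ,   GM = (Π d_ij)^(1/n_st)
```

over the n_st unordered (s, t) nitrogen pairs; 0 when no pair exists.
This n/GM form is algebraically identical to the original
λ_st = n_st/d̄_st² with d̄_st = (Π d_ij)^(1/(2 n_st)). The product is
evaluated in log space to avoid overflow on long distances.

### 2.3 Atomic weightings

- **s — Kier–Hall intrinsic state**: I = ((2/L)²·δv + 1)/δ with L the
  principal quantum number, δ the heavy degree, and the *generalized*
  valence delta δv = (Zv − h)/(Z − Zv − 1) for rows ≥ 3 (so terminal
  Cl → 1.3457, I → 1.0249), δv = Zv − h for rows ≤ 2.
- **c — PEOE partial charges**: classic Gasteiger–Marsili partial
  equalisation of orbital electronegativity (section 3).
- **e — Sanderson electronegativity**: per-element lookup from the
  1983 Sanderson table (raw values, not rescaled), shipped as a
  versioned CSV.
- **p — atomic polarizability**: static per-element dipole
  polarizabilities (Å³), versioned CSV; carbon = 1.67 (an older table
  value deliberately retained, see section 4).

## 3. PEOE charge model

`atomprops.peoe_charges` implements the classic 1980 damped
partial-equalisation scheme as realised in the long-established
descriptor-software lineage:

- χ(q) = a + b·q + c·q² per atom, with the classic (a, b, c) parameter
  table keyed by element and bond-order class (maximum bond order, with
  aromatic bonds counting as single; monovalent elements and S/P have a
  single class). The table in `PEOE_PARAMETERS` includes halogens
  (Cl 12.31/10.84/1.512, Br 11.44/9.63/1.31, I 9.88/7.95/0.945), sp³/sp²/sp
  carbon and nitrogen classes, and divalent S and trivalent P.
- Hydrogens are explicit graph atoms during iteration.
- Batch updates: all χ are evaluated once per iteration from the
  current charges; each bond then transfers
  dq = (χ_hi − χ_lo)/χ⁺(donor) · (1/2)^n from the less to the more
  electronegative atom, where χ⁺ = a + b + c of the donor atom, or the
  fixed 20.02 when the donor is hydrogen.
- At most 20 iterations, stopping early once no atom's absolute charge
  changed by more than 0.001 between iterations.

For the autocorrelation graph the hydrogen charges stay on their own
vertices (hydrogens are included in the graph, section 4); for the
heavy-atom-only view (`partial_charges`) hydrogen charges are folded
onto their bonded heavy atom so total charge is conserved.

One deliberate deviation from the historical software: atoms are typed
on the *perceived* (canonical) graph, not on the bond orders as written
in the input string. The historical code types a Kekulé-written
aromatic ring differently from the same ring written in aromatic
notation, which makes descriptor values depend on how the SMILES
happened to be drawn. Here both notations give identical charges —
permutation and notation invariance is tested to 1e-10 — at the cost of
a small charge difference (≈ 0.05 e on ring atoms) versus the
historical code for molecules *written* in Kekulé form. All compounds
used for validation are written in aromatic notation and are unaffected.

An alternative charge provider (`charge_provider="rdkit"`, RDKit's own
Gasteiger implementation with its different parameter table) is
available for comparison experiments; the frozen model configuration
uses `"classic"`.

## 4. Frozen descriptor conventions and the parity experiment

Descriptor names like "ATSC4c" underdetermine the number: software
packages differ on hydrogen handling, pair ordering, parameter tables
and charge models. To pin the conventions, the five model descriptors
were computed here under all convention combinations and compared, over
a 40-molecule probe set spanning the chemistry of interest
(pyrimidines, uracils, haloalkyl/alkoxy/benzyloxy substituents), against
the reference descriptor implementation from which the model's
descriptor names originate. One combination reproduces the reference to
machine precision (maximum absolute difference ≤ 2 × 10⁻¹³ across all
four weighting schemes, and ≤ 1 × 10⁻¹⁶ for MDEN), and that combination
is frozen as the default `DescriptorConfig`:

| Choice | Frozen value |
| --- | --- |
| hydrogens in the autocorrelation graph | **included** as vertices with their own weights (`include_hydrogens=True`) |
| hydrogen intrinsic-state weight | 1.0 (the Kier–Hall index is defined on heavy atoms; hydrogens carry unit weight) |
| pair ordering | **unordered** pairs in both ATSC sums and Δ_k (`ordered_pairs=False`; the ordered convention doubles ATSC and leaves AATSC unchanged — both are available) |
| charge model | classic PEOE as in section 3 (`charge_provider="classic"`) |
| Sanderson EN table | raw 1983 values |
| polarizability table | older CRC-style values with C = 1.67 Å³ (the reference implementation's table; newer recommended values, e.g. C ≈ 1.76, change ATSC6p and are **not** used) |
| intrinsic state beyond row 2 | generalized δv (not the δv = 7 halogen shortcut) |
| atomic weights | 2005 conventional atomic-weight table (this, not a newer table, reproduces the printed MW = 280.06 for the iodinated compound 40) |

Under this frozen configuration the blind predictions are:

| Compound | Published predicted pIC50 | This package |
| --- | --- | --- |
| 41 | 5.38919 | 5.38885 |
| 42 | 6.63909 | 6.63963 |
| 43 | 3.7424  | 3.74273 |
| 40 | 5.05808 | 4.85862 |

Compounds 41–43 agree to ≈ 5 × 10⁻⁴ pIC50 units (residual rounding in
the five printed coefficients accounts for the gap). Compound 40 does
not: even the reference descriptor software yields 4.859 for the
2,4-dione tautomer as specified by its name and SMILES, so the printed
5.05808 cannot be reproduced from that structure and most plausibly
reflects a different tautomer or structure in the original input. The
package reports what the stated structure gives. Only compounds 41 and
43 carry quantitative acceptance targets.

## 5. BMLR selection

Forward selection in the published workflow's style:

1. prune descriptors with missing values or zero variance;
2. fit all descriptor pairs whose pairwise squared Pearson correlation
   is below 0.6 (the noncollinearity criterion) and keep the top 20 by
   R²;
3. grow each seed greedily, adding at each step the descriptor that
   maximises R² subject to noncollinearity with the current subset and
   to every coefficient passing |t| ≥ 2.0, stopping at max_k (default
   5) or when no admissible addition remains;
4. report the best subset, refitted in natural scale.

The search runs on centered, unit-variance descriptors; the natural
scale refit has identical fitted values (asserted to 1e-10 in the test
suite). Ties in R² break by larger minimum |t|, then lexicographic
descriptor names — the selection is fully deterministic. The beam width
(20) and significance gate (|t| ≥ 2.0) are documented defaults; the
collinearity threshold 0.6 is part of the method's definition.

Validation statistics: R² = 1 − RSS/TSS; s² = RSS/(N − k − 1);
F = (R²/k)/((1 − R²)/(N − k − 1)); q²_LOO = 1 − PRESS/TSS with PRESS by
the hat-matrix shortcut Σ(e_i/(1 − h_i))², cross-checked against the
explicit N-refit loop. External R²_test defaults to the squared Pearson
correlation between predicted and observed test activities; the
predictive form 1 − RSS_test/TSS_test is selectable and every report
carries the convention label, since the two differ off the identity
line.

## 6. Train/test split

The "intuitive-rational" split works per source group (assay): sort by
increasing activity (ties broken by name), allocate per-group test
counts by largest-remainder proportional allocation of
round(fraction × N), and pick test members at evenly spaced ranks
`int(j·(g−1)/(m+1) + 0.5)`, nudged off the extremes, with upward
collision resolution. The least- and most-active compound of every
group always stay in training; groups smaller than 3 contribute no test
compounds. On groups of (5, 15, 19) at fraction 0.2 this yields the
31/8 partition used to fit and validate the published model.

## 7. Applicability domain

Leverage of a query x against the training matrix X (intercept column
appended): h = x′(X′X)⁻¹x, computed via a linear solve rather than an
explicit inverse. Critical leverage h\* = 3(k + 1)/N (0.581 for k = 5,
N = 31), reported to 3 decimals. Residuals are standardized as e/s by
default (the internally studentized e/(s√(1 − h)) is selectable) and
flagged at the 2σ/3σ bands. The Williams-plot data export and an
optional matplotlib plot are provided.

## 8. Synthetic data: scope and limits

`pyrimqsar.synthetic` generates substituted pyrimidines from a small
grammar (uracil-2,4-dione, 2,4-dimethoxy- and 2,4-dichloropyrimidine
scaffolds with N-1/N-3/C-5/C-6 substituents) and plants activities
y = β′d(mol) + ε with ε ~ N(0, σ²), by default using the published
coefficients and σ = 0.22 ≈ √0.0485. All randomness flows through one
seeded generator.

What this supports: exercising every pipeline stage offline —
descriptor computation, the 5/15/19 grouped split, BMLR recovery of a
known ground truth (≥ 4 of 5 planted descriptors in ≈ 99 of 100 noise
replicates at σ = 0.22, N = 31), and AD reports.

What it does not support: the synthetic library's descriptor
correlation structure is not the curated dataset's, so the published
training statistics (R² = 0.85, q² = 0.797, F = 29.35, s² = 0.0485,
R²_test = 0.64) are **not** reproduced by fitting synthetic data — they
require the original curated compounds, which live in an external
deposit. The generator's activities are linear in the planted
descriptors by construction; it contains no real
structure–activity information, no activity cliffs, and no censoring.
Planted-model recovery results should be read as a check of the
selection machinery, not as a statement about pyrimidine SAR.

## 9. Numerical choices

- Shortest paths, aromaticity perception and hydrogen counts delegate
  to RDKit; descriptors consume the perceived graph, so input notation
  (Kekulé vs aromatic, atom numbering) never changes a descriptor value
  (tested to 1e-10 under random atom permutations).
- OLS via least-squares (`numpy.linalg.lstsq` / statsmodels), with
  explicit rank checks; leverages via `solve` + einsum, no explicit
  inverse.
- MDEN geometric means in log space.
- Molecular weight and elemental percentages round to 2 decimals at the
  reporting boundary only; pIC50 conversion rounds only at presentation.
- All stochastic tests and generators take explicit integer seeds
  (< 2³¹); no global random state is touched.
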