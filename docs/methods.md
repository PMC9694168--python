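# Methods

## Model

The predictor estimates pGI50 = −log10(GI50 / M) for each (compound, cell
line) pair of a tumour panel from molecular descriptors alone. It assumes
(i) that structurally similar compounds — similar meaning most descriptors
within a ±5 % relative window — have similar panel activities, and (ii)
that compounds whose activity against a given cell line falls in the same
narrow potency band share a recognisable descriptor profile. Assumption (i)
drives the finger-print (FP) module, (ii) the cell-lines (CL) module.

**FP module.** For a query vector q and a training vector r, the score is

S(q, r) = #{i : both observed, |qᵢ − rᵢ| ≤ 0.05·|rᵢ|} / #{i : both observed}.

Positions missing on either side are excluded from numerator and
denominator, so S ∈ [0, 1] whenever at least one position is shared (no
shared position is an error). The window is relative to the *training*
value, which makes S deliberately asymmetric; a training value of exactly
zero degenerates to the point {0} and matches only an exact zero. The query
inherits the activity row of the arg-max training compound; ties on S
prefer the compound with more observed activities (it transfers more
information), then the lexicographically smaller id.

**CL module.** Per cell line, training compounds are partitioned by
activity into 42 bins — 40 half-open bins [4.0+0.1k, 4.1+0.1k) plus an
underflow (<4) and an overflow (>8) bin; the boundary value 8.0 belongs to
the closed top regular bin [7.9, 8.0]. Each non-empty (cell line, bin)
template stores per-descriptor mean μ and population standard deviation σ
of its members. Matching modes:

* `a` — mean of indicators 1{μ−σ ≤ v ≤ μ+σ} over usable descriptors;
* `b` — mean of exp(−z²/2), z = (v−μ)/σ;
* `c` — mean of exp(−z²/8), i.e. an effective width of 2σ.

The winning template's representative value is assigned: the midpoint of a
regular bin, or the assay clamps 4.0 / 8.0 for the edge bins (screens
report "≥ 100 µM" / "≤ 10 nM" at the dose limits, so the clamp is the
honest point estimate). Score ties prefer the template with more members,
then the lower bin index.

**Combination.** pGI50 = pGI50(FP)·S + pGI50(CL)·(1−S), per cell line. A
missing FP value (the matched compound was never assayed in that line)
falls back to the CL value; a missing CL value (no usable template) falls
back to the FP value; both missing stays missing. The combination is convex,
so the result always lies between its two parents, and a training compound
pushed through the pipeline reproduces its own experimental row exactly
(S = 1 self-match).

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| N | descriptors retained per cell line for template matching | 240 | clamped to the available columns |
| Z | max % of exactly-zero values per descriptor column | 50 | strict: a column at exactly Z % is kept |
| G | template smoothing mode | `a` | one of `a`, `b`, `c` |
| min_members | smallest member count for a usable template | 1 | sparse bins below it are skipped in matching |

Z is applied once, globally, before template building and FP matching: a
descriptor that is zero for most compounds carries no contrast under a
relative tolerance. N is applied per cell line: descriptors are ranked by
mean within-template relative dispersion — the average over non-empty
templates of σ/(|μ|+ε), ε = 10⁻⁹, ascending, ties broken by name — and the
N tightest are kept. Low within-bin dispersion is what makes a μ±σ profile
discriminative, and ranking per cell line keeps that line's 42 template
scores mutually comparable. The FP score uses the zero-filtered set but not
the per-cell-line top-N: the similarity is a whole-molecule statement with
no cell-line dependence, while N and G tune the template matcher only.

The default tuning grid crosses N ∈ {240, 360, 480, 600, 720, 800} with
G ∈ {a, b, c} at Z = 50 — 18 runs, run 1 = (240, 50, a) — and is
config-overridable. Tuning scores the CL module alone on an internal
validation subset of the training compounds (the similarity route would
trivially return their own values), and reports arg-min mean |DTV| overall,
per subpanel and per cell line, ties to the lower run id. The validation
subset is drawn with an explicit recorded seed.

## Numerical choices

* σ floor: σ ← max(σ, 10⁻⁶·max(|μ|, 1)) entrywise. Single-member and
  constant templates would otherwise accept only exact equality in mode `a`
  and divide by zero in `b`/`c`.
* Bin lookup adds 10⁻⁷ before flooring so a value stored as
  4.299999999999999 lands in [4.3, 4.4); 10⁻⁷ is far below half a bin width
  and far above double-precision representation error on [3, 9].
* Template statistics are computed over members sorted by compound id, so
  the floating-point sums — hence the serialized model — are bitwise
  invariant under permutation of the input rows.
* Models serialize to a directory of delimited text plus a JSON manifest;
  floats are written in shortest round-trip form, so load(save(m)) is
  bitwise-identical to m. Missing values are an empty field on output;
  empty and "NA" are both accepted on input.
* Cell lines with no observed activity at all are excluded from the model
  with a warning (a panel member can be dropped from a screen for lack of
  usable data); they reappear as missing predictions.
* A query sharing no observed descriptor with any training compound
  disables the FP route (S = 0, all-missing transfer) with a warning rather
  than failing the batch.

## Descriptor backends

The protocol is descriptor-agnostic; backends are registered by id and must
be deterministic, returning NaN for individual failures and an all-NaN
vector for an unparsable structure (the batch never aborts, and results are
cached by (backend id, structure payload)). The shipped default `rdkit2d`
computes RDKit's full 2D descriptor list (~210 descriptors) without any
geometry optimisation; 3D-capable backends can be registered where
conformer-dependent descriptors are wanted. `toy-counts` (heavy atoms,
rings) supports tests and examples. Precomputed matrices can bypass the
backend entirely, which is also how descriptor sets from external software
are used.

## Synthetic data

The generator emulates exactly the structure assumption (ii) above: each of
the 42 bins gets a latent mean vector, drawn uniformly in [20, 40]ᵈ and
re-drawn until every pair is at least `between_separation` apart (default
2·√d, keeping the typical per-descriptor offset between two templates near
2 within-template standard deviations at any dimensionality). Bin means are
shared across cell lines — a compound has a single descriptor vector, so
per-cell-line-independent profiles would be mutually inconsistent — and a
compound therefore occupies one bin panel-wide, with an independent
within-bin activity draw per cell line (uniform in the bin; the open-ended
edge bins sample 3–4 and 8–9). Descriptor noise is diagonal Gaussian
(`within_sigma`, default 1), matching the per-descriptor μ±σ model the CL
module assumes. Defaults: 240 compounds × 60 descriptors over nine cell
lines in three subpanels, 10 % near-duplicates, 10 % missing activities.

Near-duplicates clone a parent with ≤1 % multiplicative descriptor jitter —
safely inside the 5 % similarity window — and inherit the parent's activity
row *and* missingness mask: a duplicate is the same molecule with the same
assay history. (Independent masks would let an S = 1 tie transfer a
differently-masked row and break the self-consistency identity through no
fault of the predictor.) Query draws from the same latent means carry true
bin labels for recovery scoring; a `sigma_scale` factor inflates their
spread to emulate increasingly novel scaffolds.

What the generator does **not** emulate: real descriptor distributions
(heavy tails, discreteness, zero-inflation), correlated descriptors,
multi-scaffold activity bins, cell-line-specific structure–activity
relationships, and realistic NCI-60 activity marginals (most screened
compounds are inactive). Passing tests therefore demonstrate the
correctness and internal coherence of the machinery — binning, matching,
weighting, aggregation, tuning — not prospective accuracy on real screens,
which depends on the descriptor backend and training corpus supplied.

## Validation harness sizes

The shipped checks run at desk scale: 120–300 compounds, 12–60 descriptors,
nine cell lines; 1000 random pairs for the similarity oracle; 500 fresh
queries for bin recovery; 20 random fixtures for member-count conservation;
60 duplicates and 150 novel scaffolds (at twice the within-template spread,
over seven well-populated regular bins) for the module-comparison check.
At those sizes the template module recovers planted bins within ±1 bin for
≈99 % of queries, the similarity route is exact on duplicates (mean |DTV|
0) while the template route pays the ≈0.025 half-bin quantisation cost, and
the ordering reverses on novel scaffolds (FP ≈ 0.033 vs CL ≈ 0.025): the
two modules fail in complementary ways, which is the rationale for blending
them.

## Known limitations

* The three smoothing modes and the representative value of a winning
  template are conventions fixed here (hard indicator, σ- and 2σ-kernels;
  bin midpoints with edge clamps); other conventions are defensible and
  would need revisiting against reference outputs if any became available.
* Whether N, Z apply globally or per cell line is a design choice here
  (Z global, N per cell line).
* Edge-bin predictions are clamped point estimates; compounds far outside
  the assay range incur irreducible |DTV| against their true values.
* The FP route uses the single best match; no k-nearest generalisation.
* Templates are diagonal (per-descriptor μ, σ); descriptor covariance is
  ignored by design.
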