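# Methods

This note documents the models, stand-ins, numerical choices and
limitations of `gemscout`, in the package's own terms.

## Network model

A network is metabolites (with compartments and an optional boundary
flag), reactions (stoichiometry, flux bounds, GPR rule, pathway labels),
a growth objective, a medium, and a set of goal compounds. Conventions:

- **Boundary metabolites** (the SBML `boundaryCondition` analogue) sit
  outside the mass balance and represent the extracellular pool. This is
  what lets a three-reaction chain `A_ext → A → B → biomass` be a valid
  FBA model.
- **Uptake reactions are written import-forward**; the `medium` maps a
  reaction id to its forward (uptake) capacity. A medium value of 0
  forbids uptake while leaving secretion to the reaction's lower bound —
  so ethanol can be exported during the glucose phase even though it is
  not a carbon source there.
- **Phases**: the glucose phase is the network default (glucose-rich
  medium). The ethanol phase closes the glucose exchange entirely,
  bounds (0, 0), and sets the ethanol uptake capacity to 1.0. The 1.0 is
  interpreted as an uptake bound magnitude in mmol/(gDW·h).
- GPR rules are boolean trees parsed from strings like
  `g1 and (g2 or g3)`; an empty rule means no gene requirement
  (spontaneous reactions). Default bounds are (−1000, 1000) for
  reversible and (0, 1000) for irreversible reactions.
- `remove_reactions` may remove the objective reaction (an ensemble
  could, in principle, target it), so objective existence is checked
  when FBA runs, not as a standing invariant.

## Logic simulation

Reaction rules are definite Horn clauses, so forward chaining computes
the same deductive closure an automated theorem prover would, without
the dependency. Reversible reactions become two directed rules gated by
the same GPR (logical availability has no flux sign); a direction exists
only if its flux bound allows it. The fixpoint is reached in at most
|rules| + 1 sweeps and is independent of iteration order (the rules are
monotone). Stoichiometric coefficients are ignored: presence is binary.

A gene counts as expressed when it appears in the GPR of an active
reaction and is not deleted (`gene_expression_rule="all_gpr_genes"`,
the default). The stricter alternative `satisfied_leaves` counts only
leaves on satisfied branches; the right choice is not decidable from
first principles, so both are exposed.

Currency metabolites (ATP, H₂O) would trivially unlock reactions in a
real genome-scale model; the toy networks avoid the issue, and a
real-model run would need a currency-metabolite policy. This is a known
limitation, not handled here.

## Flux balance analysis

`scipy.optimize.linprog` (HiGHS) with a fixed variable order, so
repeated runs agree bit-wise. Presence uses |v| > threshold (default
10⁻⁹ mmol/(gDW·h), **strict** inequality): absolute value, because a
reversible reaction carrying negative flux is active regardless of sign.
FBA optima are degenerate; the default presence is therefore
solution-dependent (one deterministic solution). An optional
flux-variability mode (`FbaConfig(fva_presence=True)`) counts an entity
present if any optimal solution activates it, at the cost of 2 LPs per
reaction. An unbounded objective raises (it signals a missing exchange
bound); an infeasible model is reported with status rather than raised.

## Disruption ensemble

Defaults: 500 simulations, removing between r_min and r_max reactions
drawn uniformly without replacement from the target set; subset size is
drawn before members so draws are reproducible given the seed. At
genome scale the removal bounds would be 5–12; the toy-network pipeline
uses 1–3, scaled to its pathway sizes (3–4 reactions each).

Aggregation: `delta = freq − baseline` (mean presence under disruption
minus undisrupted presence), direction = sign of delta outside a
dead-zone τ (default 0) — the simplest rule consistent with "averaging
over repeated simulations". τ > 0 exposes robustness: τ = 1/n_sim
ignores single-draw flukes.

Draws that kill growth are kept by default (`nongrowth_policy="keep"`),
with the growth fraction reported; `reject_resample` redraws them and
`flag` records them. An infeasible disrupted FBA model contributes empty
presence (an infeasible model supports no flux). With the logic
simulator every delta is ≤ 0 (removal cannot add deductive presence);
positive deltas can arise only from FBA rerouting.

The framing assumes disruption *harms* the target pathways; a
positive-regulation hypothesis would need a different target set. The
target-set choice is the only hypothesis knob.

## Differential analysis (stand-ins)

These stages are deliberately simplified stand-ins for DESeq2 and
notame-style pipelines — no dispersion shrinkage across features, no
fold-change shrinkage, no drift correction. They exist so the pipeline
has a self-contained differential stage whose calibration is testable on
synthetic data, not to reproduce those tools.

- **Transcripts**: median-of-ratios size factors (geometric reference
  over all-positive features; all-zero features flagged and passed
  through), then a Wald-type statistic on the ln-scale group-mean
  difference with a pooled method-of-moments NB dispersion
  (`var = µ + α µ²`, α clipped to [0, 100]), pseudocount 0.5, referred
  to a t distribution with n₁+n₂−2 df. The t reference (rather than
  normal) keeps the type-I error near nominal at the default 4
  replicates — verified at 0.05 ± 0.02 by the acceptance suite, not
  tuned to it. Significance convention: BH FDR < 0.05.
- **Metabolites**: intensities are log2-transformed (the field norm;
  it also makes the reported fold-change natural), then an
  equal-variance two-sample t-test per feature (the two-group linear
  model). Zero variance in both groups → p = 1 with a flag.
  Significance convention: p < 0.1, reflecting metabolomics noise.
  Only the group term is modelled; real designs may need batch or
  injection-order covariates.
- BH adjustment via statsmodels.

## Consensus enrichment

- **Fisher**, two-sided exact (scipy), oracle-tested against full
  hypergeometric enumeration on every table with n ≤ 30.
- **Boschloo** is hand-implemented because the scipy version uses a
  one-sided statistic: here the statistic is Fisher's two-sided p and
  the p-value is the supremum over a 99-point nuisance grid of
  P(statistic ≤ observed) under Binomial row sampling. By construction
  p_boschloo ≤ p_fisher (property-tested on 1000 random tables).
- **Preranked GSEA**: classic weighted running sum (weight exponent 1
  on |stat|), ranking by the signed Wald/t statistic from the
  differential stage (the ranking metric is configurable; no canonical
  choice exists). Ties break by feature id. The null permutes gene
  labels; p has resolution 1/(n_perm+1). The report is direction-split:
  the direction opposite the observed enrichment score is
  not-applicable. This is not the multilevel split-sampling algorithm
  of the fgsea package — same score, simpler null, with the p-value
  floor documented.
- A pathway is significant when any of the three p-values < 0.05; the
  exact tests are the conservative arm, the rank test the sensitive one.

## Phenomics

ln(OD560) is smoothed with a centred rolling median (default window 5
points; the first/last two points are left raw — on monotone noise-free
data the median is the identity, so this choice is exact there), then
differentiated with central differences (one-sided at the ends).
µ = max derivative, carrying capacity = max OD (ln is monotone, so the
argmax equals that of max ln OD). Noise-free exponentials are recovered
exactly; a smoothed-derivative estimate like this stands in for
Gaussian-process curve fitting, which is out of scope.

The permutation test uses T = median(a) − median(b), n random
relabelings (default 10,000), and p = (1 + #{|T*| ≥ |T_obs|}) / n,
clipped to 1 — the add-one rule, so p ≥ 1/n. With zero within-group
variance the median statistic loses resolution (many relabelings tie);
that is a property of the test, not a bug.

## Synthetic data

The generators state a fixed world; their defaults are not tuning
knobs.

- **Growth curves**: logistic skeleton per strain with (r, K) solved
  from two stated constraints — the continuous-time maximum specific
  growth rate equals µ (0.402 h⁻¹ reference, 0.450 h⁻¹ mutant) and the
  OD at 24 h equals the stated value (0.265 / 0.338) — from initial
  OD 0.05, sampled every 20 min. Measurement noise is multiplicative
  log-normal (default sd 0.02, a typical plate-reader scale). A
  two-segment diauxic option joins a slower second logistic at a
  configurable shift time (default 12 h) with the same 24-h
  calibration; the single-phase default keeps the analytics clean.
  What a green test establishes: the estimators recover the stated
  physiology on this idealised world; real curves have lag phases,
  plate effects and heteroscedastic noise that this world omits.
- **Transcripts**: NB counts, log-normal baseline means (log-mean
  log(100), sd 1.2), log-normal library factors (sd 0.1), dispersion
  0.05 (a typical bulk RNA-seq scale), effects as 2^log2FC on the
  mutant group mean in the specified phase; 2000 features, 4 replicates
  per group by default (real replicate counts per pooled group are a
  design choice, not derivable).
- **Metabolites**: log-normal intensities (base log2 uniform 12–22,
  replicate sd 0.5), effects additive on the log2 scale. Two-stage
  dropout calibrated to the 85 → ~14 identified → ~9 passing-QC
  attrition of untargeted LC-MS on short-chain organic acids; both
  rates are overridable, and the truth table records which features
  survived each stage. Per-run effect estimates carry SE ≈
  sd·√(2/n) ≈ 0.35, so recovery tolerances are asserted on medians
  across generator seeds.

## Pipeline

`run_pipeline(RunConfig)` executes network → synthetic data →
disruption ensembles (both simulators × both phases) → differential →
enrichment → phenomics → evaluation, writing every intermediate as
TSV/JSON plus a manifest with per-stage timings, sha256 checksums and a
config hash. Per-stage seeds are fixed offsets from the run seed;
identical configs reproduce identical files.

Direction-prediction accuracy is computed over entities that are
predicted differential *and* measured (`all_measured`, the default
denominator; `significant_only` restricts to empirical FDR < α — both
readings are recomputable from the emitted join tables, since no
canonical denominator exists). An empty evaluable set reports
not-applicable rather than 0.

## Known limitations

- The toy network has no currency metabolites, no compartmental
  thermodynamics, and integer-ish stoichiometry; it is a structural
  stand-in, not a model of yeast.
- SBML/MAT ingestion is out of scope; the JSON dialect is documented in
  `gemscout.network`.
- Abductive hypothesis generation (theory repair) is out of scope; only
  deletion states are simulated.
- FBA presence depends on the optimum chosen unless the (slower) FVA
  mode is enabled.
- The GSEA p-value floor is 1/(n_perm+1); very small pathway p-values
  are censored at that resolution.
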