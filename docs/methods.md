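# Methods

## Problem and scope

`maitrep` analyses the T-cell receptor (TCR) repertoire of mucosal-associated
invariant T (MAIT) cells from two kinds of sequencing data collected in
IBD-vs-healthy cohort designs:

1. **single-cell paired α/β records** from colon biopsies — each sorted cell
   carries at most one α and one β chain with V/(D)/J gene calls, a CDR3
   junction at nucleotide and amino-acid level, and a productivity flag, as
   produced by IMGT-style alignment of Sanger amplicons;
2. **bulk β-chain repertoires** from blood sorts — one row per unique
   rearrangement with a template count, as exported by commercial deep
   β-chain sequencing.

The pipeline covers canonical-MAIT filtering, clonotype expansion and
sharing, colon↔blood overlap accounting, public-sequence partitioning by
cohort, and repertoire diversity/overlap statistics. Upstream steps (base
calling, V(D)J alignment) and downstream rendering (circos plots, pie
charts) are out of scope: the pipeline consumes aligner output and emits
the edge lists and frequency tables such plots are drawn from.

## Canonical-MAIT filter

MAIT cells are defined by a semi-invariant α chain: TRAV1-2 joined to
TRAJ12, TRAJ20 or TRAJ33. Because surface-marker sorting of colonic
lymphocytes is impure, each sorted cell is classified at sequence level: a
cell is *canonical* iff its α chain is present, productive, uses TRAV1-2
(TRAV1-1 is rejected; alleles and zero padding are ignored) and one of the
three canonical TRAJ genes, **and** its β chain is present and productive —
the "productive paired" requirement. Failure reasons are assigned in the
fixed order `missing_alpha → nonproductive_alpha → wrong_trav → wrong_traj
→ missing_beta` so counts are reproducible; a present-but-nonproductive β
maps to `missing_beta`. An `alpha_only` flag waives the β requirement for
α-only tabulations. The per-sample summary reports only cells with at least
one readable chain (wells that yielded no sequence are invisible to the
input format and therefore not a denominator the pipeline can know).

## Clonotype identity — two deliberate levels

* **Within the single-cell colon data**, clonotype identity is the full
  paired nucleotide key: (V, J, CDR3 nt) of both chains. This is the
  strictest available definition and is what "the exact same TCR alpha and
  beta sequences" means operationally. Cells whose CDR3 contains an
  ambiguity base `N` are excluded from exact matching and logged.
* **For any comparison involving bulk blood data or crossing donors**,
  identity is the β-chain CDR3 amino-acid sequence alone: bulk data carries
  no α chain, and publicity is conventionally counted on CDR3β amino acids
  without conditioning on V/J. Both levels are exposed in the API so the
  choice is auditable.

Sharing edges connect unordered pairs of cells with identical paired
clonotypes; classes mirror the usual plot colouring (within-HC-biopsy,
within-CD-inflamed, within-CD-uninflamed, CD-cross-inflammation). Cross-donor
edges are suppressed unless explicitly requested.

## Colon↔blood overlap accounting

For each stratum (HC, CD all, CD non-inflamed, CD inflamed, total) the
unique colonic CDR3β amino-acid sequences are counted; a sequence is
`in_both` if present in *any* blood repertoire, `autologous` if present in
a carrier donor's own blood, `allogeneic` if present in the blood of any
non-carrier donor (blood from either cohort counts). The categories
overlap by design — a sequence found in both autologous and allogeneic
blood increments all three. "CD all" and "total" de-duplicate sequences
seen in both of a donor's biopsies. Percentages are integer percents
rounded **half away from zero**; this rule reproduces published tables of
this shape from their integer counts (round-half-to-even does not, e.g.
1/8 must print 13%). Colon donors without a blood sample are logged; their
sequences still participate in allogeneic comparisons.

## Diversity and overlap statistics

* **Simpson clonality** uses the unbiased estimator
  `Σ nᵢ(nᵢ−1) / (N(N−1))` — the probability that two distinct cells drawn
  without replacement share a clonotype. This form is chosen over the
  plug-in `Σ pᵢ²` because only it satisfies both stated boundary
  conventions: exactly 1 for a monoclonal sample and exactly 0 when every
  cell is unique. Undefined (error) for N < 2.
* **Morisita overlap** defaults to the frequency-based Morisita–Horn form
  `2 Σ pᵢqᵢ / (Σ pᵢ² + Σ qᵢ²)`, which is robust to unequal sample sizes
  and is bounded in [0, 1] with 1 for identical frequency vectors and 0
  for disjoint supports. The classical count-based Morisita index is
  available behind `variant="classical"`; note it can exceed 1 on finite
  identical samples (self-comparison of k equal clones of size n gives
  `(kn−1)/(k(n−1))`), which is why it is not the default. Blood diversity
  and overlap operate on β amino-acid clonotypes, matching the publicity
  analysis.
* **Consensus motifs** restrict to sequences of the modal length (ties
  resolve to the shorter length), then per position emit the single
  residue if its frequency reaches the majority threshold (default 0.5),
  else the two most frequent residues bracketed (`[M/R]`) if they jointly
  reach it, else `X`. Support is the fraction of modal-length sequences
  matching the expanded motif. The thresholds are tunable.
* **Gene usage** is per cell by default; `per_clonotype=True` counts each
  paired clonotype once, removing clonal-expansion weighting.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes: by default
10 HC + 10 CD donors, one biopsy per HC donor and paired
uninflamed/inflamed biopsies per CD donor (80 cells each), and bulk blood
repertoires for the first 8 donors of each cohort. Blood sorts of up to
50,000 cells are represented at 1:100 scale (500 cells per donor) so the
default cohort simulates in about a second; the scale factor changes
clone-count granularity but none of the exact-recovery properties.
HC biopsies carry `inflammation="uninflamed"` (endoscopically uninflamed
by design; the `not_applicable` state is reserved for blood).

Key default parameters and why:

| parameter | default | rationale |
|---|---|---|
| `canonical_alpha_fraction` | 0.45 | just under half of sorted colonic cells carry a canonical α in this sort strategy |
| `traj_weights` | TRAJ33 0.8, TRAJ12/20 0.1 each | TRAJ33 predominates among canonical MAIT α chains |
| `trbv_weights` | TRBV6-4 0.30 + TRBV20-1 0.25 (= 0.55), rest spread | the two dominant MAIT β V genes jointly exceed half of cells |
| `clone_size_law` | geometric(0.4) | simple heavy-enough tail for expansion tests; zipf available for stress tests |
| `colon_blood_autologous_rate` | 0.5 | about half of colonic sequences are also found in autologous blood |
| `colon_blood_allogeneic_rate` | 0.13 | ~13% of colonic sequences appear in another person's blood |
| `publicity_rates` | cd_only 0.24 / hc_only 0.09 / shared 0.67 | proportions of the public blood pool by carrier cohort |
| `public_pool_size` | 40 | public-sequence count scaled to the 1:100 blood depth |

Canonicity is drawn per cell (independent Bernoulli), so the cohort-wide
canonical count is exactly binomial and the 99% exact-interval recovery
test is well-posed. TRAJ and TRBV are drawn per *clonotype* (cells of a
clone share a receptor), so usage-recovery checks are performed
clonotype-weighted, where the binomial unit is the clonotype.

**Exactness of ground truth.** Every β CDR3 is drawn from a global
uniqueness registry (`C` + 8–16 random residues + `F/W`; collisions are
retried and counted), so *all* observed sharing is injected sharing:
public blood sequences, autologous/allogeneic colon↔blood overlaps and
cross-inflammation clonotypes are recoverable exactly, not statistically.
Because an autologous and an allogeneic injection can land the same
colonic sequence in two blood repertoires (making it public), the
generator derives the expected public partition from its own final
placements rather than from the configured pool alone.

**Randomness contract.** One master seed; per-donor substreams are derived
via `SeedSequence` spawn keys indexed by (cohort, donor index), so adding
a donor leaves existing donors' base records byte-identical. Cross-donor
steps (public pool, colon↔blood injection) use dedicated streams; they
couple donors by construction, which is why the add-a-donor invariance is
stated for base records with sharing rates at zero.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: V(D)J recombination biology (junctional
insertion/deletion statistics, convergent recombination), sequencing
error, true clone-size laws of MAIT populations, and biological
correlation between a donor's colon and blood beyond the injected
sharing. Recovery tests validate the *bookkeeping* of the pipeline, not
the biology of any particular cohort.

## Numerical and degenerate-input choices

* Percentages: integer, half away from zero (see above).
* Simpson/Morisita are evaluated in double precision over explicit clone
  unions; oracle tests pin them to brute-force enumeration at 1e-12.
* Duplicate chain rows: byte-identical rows are deduplicated; two
  differing productive chains on one locus mark the cell a doublet
  (dropped, logged — Sanger cannot phase them); any other conflicting
  duplicate is an error. Unparseable gene calls mark the chain
  nonproductive rather than dropping the cell.
* Empty inputs: writers refuse empty collections without `force`; an
  empty repertoire after productivity filtering and an empty canonical
  set are distinct, explicit errors (CLI exit code 4).
* Group-comparison tests (Mann-Whitney, Kruskal-Wallis) are thin
  delegations to scipy, reported unadjusted; groups below size 2 are
  skipped with a recorded reason.

## Known limitations

* The immunoSEQ column mapping defaults to template counts; whether a
  given export's abundance column holds templates or reads is a config
  choice (`column_map`), not something the pipeline can detect.
* The AIRR dialect requires the study metadata columns (donor, cohort,
  tissue, inflammation) alongside the standard rearrangement columns;
  bare AIRR files need a metadata join first.
* Publicity matching ignores V/J genes by design; with very short CDR3s
  this is more permissive than a V-conditioned match.
* The classical Morisita variant is reported as computed, including
  values above 1 on finite samples.
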