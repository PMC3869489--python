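# Methods

## The activity-cliff model

An activity cliff is defined over a pair of compounds with measured
activity against the same target. Four choices fix the definition: (i) only
pairs are considered, (ii) both compounds share one target, (iii) a
structural similarity criterion, and (iv) a potency-difference criterion.
`cliffminer`'s default — and most conservative — configuration is:

- **Similarity**: formation of a transformation-size-restricted matched
  molecular pair (MMP);
- **Potency difference**: at least two orders of magnitude, ΔpKi ≥ 2.0;
- **Measurements**: equilibrium constants only.

Potency is standardized to pKi = −log₁₀(Ki in mol/L); 100 nM ⇒ pKi 7.0
exactly. Measurement kinds (equilibrium constants; IC50-type
concentrations; approximate annotations such as "% inhibition") are never
merged into one value: the survey restricts itself to equilibrium
constants, IC50-type records are dropped with a tally, and approximate
annotations cannot be converted at all. Repeat equilibrium measurements of
one compound–target pair collapse to their median pKi; compounds whose
measurements span more than 1 log unit are flagged as discordant (they stay
in the set — the flag is diagnostic, since the median of discordant values
is still the best available point estimate, but downstream users can drop
them).

All thresholds are inclusive (≥), so "at least 100-fold", "at least
0.85" and "at least 100 compounds" hold literally at their boundaries.
Boundary behavior is pinned by tests.

## Similarity engines

**MMP enumeration.** Every molecule is cut once at every acyclic single
bond between two heavy atoms; each cut yields a core and a fragment, both
carrying one generic attachment point. Production enumeration is
index-based (a map from canonical core form to the compounds and
complementary fragments producing it); compounds meeting at a shared core
with different fragments form an MMP. An independent all-pairs scan over
full fragmentation lists serves as the test oracle and must agree exactly.
When a pair shares several cores the largest core (most heavy atoms) is
retained, ties broken by lexicographically smallest canonical core, making
output deterministic and order-independent. Double and triple cuts are out
of scope: a transformation is a change at a *single* site.

Size restriction (defaults, all configurable): exchanged fragments ≤ 13
heavy atoms each, fragment size difference ≤ 8, and core ≥ 2× the heavy
atoms of each fragment. These bounds keep transformations small and
chemically interpretable; they are echoed in every run manifest because
MMP-based results are meaningless without them.

**Fingerprints.** Two 2D representations: the public 166-key structural
fingerprint, and circular atom environments of bond diameter 4 (radius 2),
both taken as feature *sets* with Tanimoto similarity
Tc = |A∩B| / |A∪B|. Default thresholds are Tc ≥ 0.85 (structural keys) and
Tc ≥ 0.56 (circular); the latter is the quantile-equivalent of the former —
the value at which the same fraction of compound pairs qualifies.
`calibrate_equivalent_threshold` recomputes such equivalences: given pairs
scored under both representations and a reference threshold, it returns the
largest target-side value t such that the fraction of pairs with target
similarity ≥ t is at least the reference fraction. Over the reals this
supremum is attained at the k-th largest target value (k = reference count
at or above the threshold), so the fractions agree within 1/N exactly
(ties can only push the match fraction higher). Degenerate edge: if no
reference pair reaches the reference threshold the largest observed target
value is returned. Two empty fingerprints compare as Tc = 0 with a warning
(0/0 is undefined; 0 avoids manufacturing similarity between featureless
inputs).

Stereochemistry is preserved in canonical forms (so enantiomers are
distinct compounds, required for chirality-cliff categorization) but
ignored by both fingerprints, which are graph-derived.

**Cliff categories.** Chirality cliff: identical molecular graphs,
different stereochemistry. R-group cliff: identical Bemis–Murcko-style
scaffolds (frameworks after removal of terminal substituents). Core-change
cliff: everything else. Acyclic molecules have an empty-flagged scaffold;
two acyclic analogs therefore compare as same-scaffold (R-group), the
literal reading of the rule.

## Networks, survey, pathways

**Isolated vs coordinated.** In the per-target cliff network (cliff-forming
compounds as nodes, cliffs as edges), a cliff is isolated iff its connected
component has exactly 2 nodes; equivalently both partners have degree 1 —
the two readings coincide for cliff networks and the component reading is
implemented. Isolated% + coordinated% = 100 whenever cliffs exist.
Potency coloring interpolates linearly from red (component-set minimum pKi)
through yellow (midpoint) to green (maximum), normalized per network; an
all-equal network colors mid-yellow with a warning.

**Survey.** A target set qualifies when ≥ 100 unique compounds (by
canonical structure) with equilibrium constants remain after filtering.
"All compounds must have equilibrium constants" is read as *restrict the
set to the compounds that do*; the stricter discard-the-target reading is
available via `require_all_equilibrium`. Per target: cliff% = cliffs /
qualifying similar pairs × 100 (qualifying = size-restricted MMPs, or pairs
at/above the Tc threshold); compound% = cliff-forming compounds / set size
× 100. Aggregation is the unweighted mean over targets — each target is one
observation regardless of its pair count — with a pair-weighted rate
reported alongside. Targets with zero qualifying pairs are excluded from
means and tallied. Quartiles use linear interpolation between order
statistics, with the interpolation formula stated in the docstring (and
implemented directly rather than through a library call) so that summaries
are reproducible bit-exactly. The size–frequency table flags sets of ≥ 200
compounds and reports the variance of cliff% separately below/above that
marker: small sets fluctuate for statistical reasons, larger sets are
expected stable.

**Progression.** A cliff's year is the later of its partners' report
years. The cliff counts as *progressed* iff its highly potent partner has
at least one analog (size-restricted MMP neighbor) reported strictly later
— same-year reports carry no temporal ordering, hence no evidence. Any
analog counts by default; a minimum-potency filter for analogs is available
but off (the looser reading is the defensible default when the restriction
is not part of the rule).

**Pathways.** The analog graph spans *all* compounds of a target set with
size-restricted MMP edges. The top decile is the ⌈0.1·N⌉ most potent
compounds, ties at the cutoff included. A pathway succeeds iff a top-decile
compound is reachable from the start; the witness is a shortest path, and a
start already in the decile succeeds with a length-0 path (reported
separately). No potency-monotonicity constraint is imposed along paths; a
monotone variant was considered and left out of the default because the
success criterion is reachability of potent compounds, not the shape of the
route. Success rates are compared between cliff compounds and compounds in
no cliff (disjoint by construction).

## The synthetic-data generator

The generator emulates the *shape* of a curated bioactivity extraction,
not its chemistry: target sets of 120 compounds (default; 3 sets), analog
series of 10 built from one ring-system scaffold with one varied small
R-group, Ki values written in nM spanning several log units, and report
years over 2000–2012.

Planting is exact by construction:

- every within-series pair differs at a single site, so its MMP status is
  certain, and R-groups ≤ 3 heavy atoms on scaffolds ≥ 6 heavy atoms keep
  every within-series transformation inside the default size rules;
- scaffolds are mutually non-overlapping ring systems, so cross-series
  pairs can only share trivially small cores that the core-ratio rule
  rejects — a post-generation audit re-runs the MMP enumeration and
  requires the found size-restricted MMPs to equal the planted pairs
  exactly (a violation shifts the seed and regenerates; bounded retries);
- cluster series carry 2 highly potent hubs over 8 lowly potent spokes:
  hub−spoke ΔpKi ∈ [2.1, 3.4] (cliffs), within-tier spreads ≤ 0.7, so no
  noise realization can cross the 2.0 threshold in either direction;
  isolated plants are 2-compound series with one cliff; plain series have
  spread ≤ 1.4 and no cliffs;
- the timeline plants all three progression situations per set: one
  cluster whose second hub arrives two years after the rest (progressed
  cliffs for the first hub), one reported entirely in a single year, and
  one whose hubs arrive last; ground-truth statuses are derived at
  generation time by direct application of the progression rule to the
  planted series, independent of the pathway module;
- cluster bases sit above the plain-series potency window, so top-decile
  membership concentrates in cliff series and the cliff-dependent pathway
  success rate exceeds the cliff-independent one by construction — the
  direction, not the magnitude, of the real-data finding.

Per-set planted rate under the defaults: 50 cliffs over 512 analog pairs
(9.77%). What passing tests on this material shows: the detection,
classification, survey and pathway machinery is exact on inputs whose
ground truth is known with certainty. What it does not show: real-data
cliff rates, which depend on the actual chemistry and curation of a
database extraction; the generator makes no attempt to match medicinal-
chemistry diversity, realistic property distributions, assay noise at the
threshold boundary, or measurement-type mixtures beyond what the filters
need.

## Numerical and interface conventions

- Canonicalization is delegated to the cheminformatics toolkit's canonical
  SMILES (stereo-aware); duplicate detection uses that form. Re-
  standardization is idempotent (tested).
- Unit strings are matched case-insensitively over M, mM, µM/uM, nM, pM;
  unknown units reject the record with a logged tally. Non-positive or
  non-finite values reject the record.
- Output tables are written with `repr`-precision floats and canonical row
  order (target id, then compound-id pair); manifests serialize with
  sorted keys. Two runs with the same inputs and seed are byte-identical,
  and cliff tables round-trip through their reader exactly.
- Transformation direction is normalized from lower to higher canonical
  fragment encoding; compound pairs are stored with id_a < id_b.
- Degenerate inputs: empty cliff list → empty network; all-equal pKi →
  whole decile flagged degenerate / mid-color warning; empty compound
  groups → undefined (None) rates, never 0.

## Problem sizes

Default verification scales, chosen to exercise every code path while
keeping the full suite in seconds: oracle equivalence on 100 random sets of
≤ 20 molecules; isolation classification on 200 random graphs of ≤ 200
edges; calibration and quartile checks on 1,000-element samples; planted
recovery, progression and pathway checks on 3 × 120-compound collections.

## Known limitations

- Single-cut MMPs only; multi-site transformations are not enumerated.
- 3D/binding-mode cliff definitions and selectivity cliffs (two-target
  potency ratios) are out of scope, as is any database client: the
  pipeline consumes prepared tables.
- The structural-key dialect is the toolkit's public 166-key
  re-implementation; numbers from vendor key sets will differ slightly.
- Active/inactive mode requires an explicit confirmed-inactive flag; a
  missing potency value never implies inactivity, so data without such
  flags cannot use this mode.
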