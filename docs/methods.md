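# Methods

## Problem and data model

Preoperative glioma MRI in the BraTS convention comes as four co-registered,
skull-stripped channels (T1, T1Gd, T2, FLAIR) resampled to 1 mm isotropic
voxels, with an integer-coded expert segmentation: active enhancing tumour
(AT), merged necrosis / cysts / non-enhancing tumour core (NCR+NET), and
oedema / infiltrated tissue (ED). The postoperative two-label protocol keeps
contrast-enhancing tumour (CE) and the non-enhancing T2/FLAIR hyperintense
abnormality (NE) and deliberately excludes necrosis and cysts, because those
share image features with fluid-filled resection cavities and would teach a
segmentation model to label cavities as tumour.

All operations are voxelwise or topological on the index lattice; orientation
affines are carried through untouched, and geometry mismatches between
co-analysed volumes (shape, or affine beyond 10⁻³ mm) are errors, never
silently resampled — inputs are assumed pre-registered.

Label codes on disk are explicit *dialects* (default BraTS 2021:
1 = NCR+NET, 2 = ED, 4 = AT; a 3 = AT variant is provided; output CE = 1,
NE = 2). Undeclared codes in a file abort decoding rather than being dropped.

## Conversion algorithm

With a whole-tumour mask WT that excludes necrosis (from an external model;
this package treats it purely as an input):

1. NE ← NCR+NET ∩ WT
2. NE ← NE ∪ ED
3. remove NE connected components *entirely encapsulated* by AT
4. remove NE connected clusters with physical volume < 50 mm³
5. NE ← NE ∪ ED
6. CE ← AT unchanged

Consequences relied on by the tests: CE ≡ AT voxel for voxel; ED ⊆ NE;
NE ⊆ NCR+NET ∪ ED (only NCR+NET voxels are ever removed); enlarging WT never
shrinks NE; every ED-free NE component meets the volume floor; and re-running
the conversion on its own output (NCR+NET := NE \ ED, WT := NE ∪ CE)
reproduces it.

### Operational choices

* **Encapsulation test.** "Entirely encapsulated by AT" has no canonical
  operational definition. The default is a component-boundary test: a
  component C is removed iff it does not touch the lattice border and every
  voxel outside C that is face-adjacent (6-neighbourhood) to C belongs to AT.
  This encodes "entirely surrounded" literally and is stricter than removing
  everything inside the hole-filled AT mask, which would also capture regions
  enclosed by AT but bounded partly by background; that hole-filling variant
  is available (`encapsulation_method="fill"`) for sensitivity analysis.
  Border-touching components are never removed: the surround is open there.
* **Connectivity.** Cluster filtering uses the full 26-neighbourhood, the
  common default for foreground lesions; the encapsulation boundary test uses
  the 6-neighbourhood, the strictest notion of adjacency. Both are
  configurable (6/18/26) and recorded in the audit.
* **Threshold semantics.** Strictly "less than 50 mm³" is removed; a cluster
  of exactly 50 mm³ survives. Volumes are physical
  (count × voxel volume), so anisotropic grids behave correctly; at 1 mm³
  they coincide with counts.
* **Class overlap** in the input (e.g. AT ∩ NCR+NET ≠ ∅) is rejected as a
  corrupt file, not resolved silently.
* The conversion is fully deterministic; no tie-breaking is needed.

Every run returns an audit whose counts reconcile exactly:
|NE_out| = |NCR+NET ∩ WT ∪ ED| − removed_encapsulated − removed_small +
restored_by_ED.

## Cavity detection

Each of T1Gd, FLAIR and T2 is z-normalised to zero mean and unit variance
over the brain mask (the nonzero support of skull-stripped volumes);
statistics over the full lattice would be dominated by the zero background.
The population (ddof = 0) standard deviation is used — the difference from
the sample estimator is negligible at brain scale but fixed for determinism.
Candidate voxels satisfy, strictly, z(T1Gd) < −1 ∧ z(FLAIR) < 0 ∧ z(T2) > 0;
connected components ("continuous volumes", 26-connectivity by default) of at
least 2 cm³ are reported, largest first. Because z-normalisation cancels gain
and offset, the detector is invariant under affine intensity rescaling of any
channel. Distinguishing cavities from ventricles or arachnoid cysts is out of
scope; in practice such delineations are confirmed by manual inspection.

## Evaluation statistics

* **Dice.** 2|A∩B|/(|A|+|B|). When both masks are empty the score is flagged
  undefined (NaN) and excluded from score distributions rather than scored 1,
  which would inflate medians with vacuous cases; one-sided emptiness yields
  0 naturally.
* **Cavity inclusion.** Per-cavity |prediction ∩ cavity| × voxel volume; a
  cavity counts as "included" when at least 1 cm³ (configurable) of it is
  labelled, and sub-threshold inclusions are still recorded. The mean
  included volume is reported with both plausible denominators (cavities with
  nonzero inclusion, and all cavities), since "average labelled volume per
  cavity" is ambiguous between them.
* **Clopper–Pearson.** lower = Beta(α/2; k, n−k+1), upper =
  Beta(1−α/2; k+1, n−k), with the conventional closures at k = 0 and k = n.
  The interval is conservative: coverage ≥ nominal for every true proportion.
  The tests cross-check it against an independent implementation
  (statsmodels) and verify ≥ 95% empirical coverage at n = 125 in seeded
  simulation.
* **Bootstrap.** Percentile method, 10 000 resamples by default, explicit
  seed; endpoints always lie within the observed value range. Rank-based
  two-sample testing is deliberately left to standard statistics libraries.

## Phantom generator

Phantoms emulate exactly the structures whose handling the algorithms define,
on a 64³ lattice at 1 mm³ (large enough for a > 2 cm³ cavity with margin,
small enough for sub-second generation): a brain ball (default radius 28
voxels); a concentric tumour — necrotic core, enhancing shell, oedema halo —
with nested radii; optional isolated NET islands; optional CSF-like cavities.
Channel intensities are piecewise class means (tissue 100, enhancing shell
bright on T1Gd, oedema bright on T2/FLAIR, cavity 40/40/200/40 on
T1/T1Gd/T2/FLAIR) plus seeded additive Gaussian noise (default σ = 2 in
intensity units), zero outside the brain. Identical spec and seed give
bit-identical output.

Balls are voxelised by centre-of-voxel inclusion (centre within the radius).
Structures whose exact voxel count matters — NET islands straddling the
50 mm³ rule, cavities straddling the 2 cm³ floor — are specified by count:
the ball of the n voxel centres nearest the structure centre, ties broken
lexicographically, so analytic volumes are reproducible to the voxel.

Generation validates its own feasibility: structures must be disjoint and
inside the brain, cavity voxels must clear each z-threshold by at least 0.5
standardised units after normalisation, and no non-cavity brain voxel may
satisfy the cavity rule — otherwise generation fails rather than emitting a
phantom without analytic ground truth. The two-label ground truth is derived
analytically (core excluded, sub-threshold islands excluded, halo and large
islands kept), independently of the conversion code.

What the phantoms do *not* emulate: MRI physics (bias fields, partial volume,
anatomy-shaped structures, ventricles), inter-rater annotation noise, and
imperfect whole-tumour masks. Passing phantom tests therefore demonstrates
that the mask algebra, thresholds and detector implement their definitions
exactly — not that the pipeline is robust to real-data imperfections, which
the published audit of real conversions addresses separately.

## Verification strategy and problem sizes

Besides worked examples with hand-computed values, the conversion and the
detector are checked voxel-for-voxel against deliberately naive brute-force
re-derivations (Python-set mask algebra, breadth-first flood fill, exhaustive
voxelwise predicates with plain-arithmetic z-scores) on 100 random 32³
phantoms — smoothed-noise blobs with injected enhancing shells, punctured
shells and near-threshold clusters so every rule branch is exercised. The
statistics are checked against closed forms, an independent implementation,
and seeded coverage simulations (2000 replicates at n = 125; 500-repeat
bootstrap coverage at n = 100). These sizes keep the full suite under half a
minute while covering every code path; all randomness is seed-controlled.

## Known limitations

* The encapsulation and connectivity conventions of the original conversion
  are not uniquely determined by its published description; the defaults here
  are documented choices with configurable alternatives.
* The exact lower confidence bound for 122 successes in 125 trials is
  0.93146, i.e. 93.1% at one-decimal rounding (this matches R's `binom.test`
  and statsmodels); reports quoting 93.2% reflect intermediate rounding.
* The detector inherits the rule's blind spots: cavities whose FLAIR signal
  is not suppressed, or smaller than 2 cm³, are not reported.
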