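# Methods

## The rigid base-pair model

Each base pair is a rigid body; the relative placement of two consecutive
base pairs is parametrized by six step parameters in the fixed order

    q = (shift, slide, rise, tilt, roll, twist)

translations in Å, rotations in degrees. We use the **mid-step frame
convention**: the relative rotation between frames i and i+1 is described
by a rotation vector whose (x, y, z) components in the mid-step frame are
(tilt, roll, twist), and the translation (shift, slide, rise) is expressed
in the same mid-step frame; the mid-step frame itself is frame i rotated by
half the rotation vector, with its origin at the midpoint of the two
base-pair origins. This is the dominant convention in rigid base-pair work;
it makes `midframe()` exactly self-consistent with
`compose_frames()`/`frames_to_step()` (round-trips hold to 1e-8 over 10⁴
random steps, far below any physical scale). No claim is made that results
depend on this choice — harmonic models of this class are known to be
robust to the convention, and we document rather than resolve the
sensitivity.

The elastic energy of a step of dinucleotide type s is
E = ½ (q − q⁰ₛ)ᵀ Qₛ (q − q⁰ₛ) in units of kT at room temperature. Energies
are strictly local: base i enters only steps i−1 and i, which the samplers
exploit.

### Parameter table

`src/nucmux/data/step_params.tsv` holds q⁰ and Q for the 10 distinct steps;
the other six follow by the strand-inversion transformation (sign flip of
shift and tilt, i.e. Q → EQE with E = diag(−1,1,1,−1,1,1)), applied and
re-verified on load together with symmetry and positive definiteness.

The intrinsic values are crystal-survey averages for protein-bound DNA as
commonly reproduced in the literature (e.g. GC has the smallest intrinsic
roll, pyrimidine–purine steps the largest). The stiffness matrices are a
best-effort transcription of published force constants from atomistic-MD
parametrizations: diagonal terms in the ranges 2–7 kT/Å² (shift/slide),
14–23 kT/Å² (rise), 0.014–0.07 kT/deg² (rotations), with the canonical
softness ordering (TA, CA/TG softest; AT, GC stiffest in roll) and
moderate cross-couplings (twist–roll negative; twist–slide, twist–rise,
roll–rise, tilt–shift positive) expressed as fixed correlation coefficients
of the diagonal terms. The package's tests deliberately depend only on
structural properties of the table (positive definiteness, inversion
symmetry, locality), not on the specific numbers; the emergent
positioning-rule statistics are a genuine prediction of the table, not a
fit.

`StepParamSet(strict=False)` additionally admits positive-*semi*definite
tables; the only intended use is degenerate limits in tests (an all-zero
stiffness table makes every landscape exactly flat).

## The constrained nucleosome

The 147-bp chain is forced onto the superhelix by **rigidly fixing 28
mid-step frames**, two per binding site at 14 sites — the model has no
adjustable binding strength; constraints are hard. Site centres sit every
helical repeat (10.3 bp) symmetrically about the dyad (bp 0; offsets
±5, ±15, ±26, … ±67), and each site's two fixed frames straddle the centre
three steps apart, one on either side of the minor groove. Because the
pair is rigidly anchored, any mismatch between a sequence's preferred
minor-groove geometry and the site geometry is paid in elastic energy —
this is how minor-groove width enters a model that contains only base
pairs.

The packaged constraint fixture
(`data/nucleosome_constraints_synthetic.tsv`) is **synthetic**: frames are
generated on an ideal left-handed superhelix (radius 41.9 Å, pitch 25.4 Å)
spanning 1.75 turns between the outermost constraints, with the local twist
phase anchored so the major-groove axis points radially outward at every
site centre (minor groove inward). A crystal-structure-derived fixture
would differ in detail but obeys the same schema; `load_constraints`
validates any 28-frame/14-site TSV.

`initial_state` threads an arbitrary sequence onto the constraints: the two
base pairs flanking each fixed midframe are placed symmetrically about it
with a nominal B-DNA step (the table's mean intrinsic step), gaps between
anchors are filled by interpolating the twist-detrended frames (slerp on
the residual rotation, linear origins), and the ends extend with nominal
steps. Constraints are satisfied exactly by construction; the interpolated
conformation is a smooth, finite-energy starting point that the sampler
relaxes.

## Monte Carlo

Metropolis sampling with two move families at a single effective
temperature:

* **spatial moves** — (a) a Gaussian rigid-body perturbation of one
  unconstrained base pair (affecting its two flanking steps), or (b) a
  Gaussian perturbation of the *internal* step parameters of a constrained
  pair, whose two frames are then rebuilt from the stored target midframe,
  so the constraint is preserved to machine precision by construction
  (residuals stay at ~1e-16 over 10⁵ moves);
* **mutation moves** — a uniformly chosen position gets one of its three
  alternative bases (MMC), or a uniformly chosen codon gets a uniformly
  chosen *synonymous* alternative (sMMC; Met and Trp codons are proposal
  dead ends counted as rejections; stop codons are never proposable since
  no sense codon is synonymous with a stop). All proposals are symmetric,
  so detailed balance holds with the plain Metropolis rule.

**Temperature scale.** The parameter table is calibrated in kT at room
temperature, so the acceptance rule uses β_eff = 300/T_K: "100 K" sharpens
the sequence ensemble threefold relative to room temperature. The
temperature is simulation-technical — it sets the affinity/diversity
trade-off of the sampled sequence ensemble, not a physical temperature.

**Defaults and tuning.** One sweep proposes as many moves as there are base
pairs; the spatial/mutation mix is 50/50; proposal widths start at 0.12 Å /
2° and are auto-tuned during burn-in (default 10% of sweeps) toward 40–60%
spatial acceptance; recording thins by `record_every` sweeps. Runs are
bit-reproducible from (config, seed): chunk seeds derive deterministically
from the master seed. The inner loop is a numba nopython kernel whose
rotation primitives are re-implemented for speed and cross-checked against
the scipy-based reference API in the tests.

Equilibration caveat: at the lowest effective temperatures (≈20 K) the
sampler needs several thousand sweeps of burn-in before ensemble statistics
stabilise; the temperature-ordering test uses 15 000 sweeps with 40%
burn-in for that reason. sMMC on a window whose reading frame is offset
(frame 1 or 2) mutates only the 48 fully-contained codons; the edge bases
belong to codons extending outside the window and stay fixed, keeping
protein invariance exact.

## Landscapes and excluded volume

`elastic_landscape` measures, for every dyad position along a long
sequence, the mean energy over the second half of a spatial-moves-only run
at low temperature (default 50 K, 2000 sweeps per position, annealed from
300 K over the first quarter to avoid trapping). Positions are independent,
with per-position seeds derived from (seed, position). Per-position
estimates carry an MC standard error of roughly 1 kT at these settings —
small against the ~10–20 kT undulations of typical landscapes; properties
that are exact only in distribution (e.g. strand symmetry: the landscape of
the reverse complement is the mirror image) are therefore tested with
tolerances set by that measured noise.

`effective_landscape` places hard rods of one footprint (147) on the
landscape at chemical potential μ and computes the exact equilibrium
dyad-occupancy n(s) by the standard two-pass transfer recursion, evaluated
in log space so arbitrarily large μ or deep wells cannot overflow. It is
verified to 1e-9 against direct enumeration of all rod configurations on
small lattices and to 1e-6 against the closed-form bulk Tonks density
μ = ln[ρ(1−(a−1)ρ)^{a−1}/(1−aρ)^a] at the centre of a long flat lattice
(boundary effects decay within a few footprints). The effective energy is
−ln n(s) + const, with the constant fixed so its global minimum coincides
with the elastic landscape's — the only normalization that needs no
external convention. Note μ is measured on the same absolute scale as the
landscape energies, which depends on the parameter table and constraint
geometry; values quoted for other parametrizations do not transfer
directly.

`formation_energy_delta` is the difference of mean low-temperature energies
of two 147-bp sequences under identical settings; `site_subset` restricts
the energy sum to the steps spanned by a contiguous block of binding sites,
as a proxy for sub-nucleosomal (tetramer-bound) formation energies — which
block to use is exposed as a parameter rather than guessed.

## Sequence statistics

Profiles are indexed by the step's left base pair in dyad coordinates
(−73…+72), so groove positions derive from the constraint geometry rather
than from hard-coded figures. `periodicity_summary` refines the dominant
DFT bin by maximizing the continuous-period amplitude and reports
(period, amplitude, phase-relative-to-dyad) of the best-fit cosine
a·cos(2πs/p − φ). The named motif groups ({GC}, {AA,TT,TA}, {AA,AT,TA,TT},
{CC,CG,GC,GG}) are presets.

## Nucleosome–amino-acid correlation analysis

Dyad maps are tab-separated (chrom, pos, score, noise) records; records
with score/noise ≤ 1.5 are discarded by default (zero-noise records are
dropped with a warning since their ratio is undefined). For every retained
dyad, the 147-bp window dyad±73 is scanned: in coding mode each in-frame
CDS codon whose 5′ base lies inside the window increments a 64×147 count
matrix at that base's window offset, measured 5′→3′ in the *gene's*
orientation (this makes the analysis exactly invariant under mirroring the
genome); in non-coding mode all fully-intergenic trinucleotides are
counted, forward strand by default (a both-strands mode, with offsets
measured 5′→3′ per enumerated strand, is available and is the
mirror-invariant variant). Codons split across introns are skipped; codon
placement uses spliced coordinates, window overlap genomic ones.

Synonymous codons are lumped into 20 amino-acid classes (stop codons kept
as a separate 21st row, excluded from analyses; counts are conserved).
Profiles are trimmed from 147 to 130 positions: 3 bp off the left terminus,
4 bp off the right, and the central 10 bp spanning the dyad (1-based window
positions 69–78; the central trim of an asymmetric-total trim cannot be
dyad-symmetric, and this centring is the documented choice). 130 is
divisible by the 10-bp repeat, so the DFT index k = 13 is exactly the
10-bp signal. Amplitudes are |DFT|/√130 of the mean-normalized profile
(so Σₖ aₖ² = length × variance); since the same normalization is applied to
coding and non-coding profiles, the coding-vs-non-coding contrast is
normalization-invariant. The contrast reports, per amino acid, the pair
(A₁₀ inside genes, A₁₀ outside genes) and how many of the 20 fall below the
diagonal.

## Synthetic data

`toy_genome` builds multi-chromosome genomes with non-overlapping
single-CDS ORF genes (ATG…stop, no internal stops) on both strands; default
2 × 60 kb with a 45% genic fraction and 300–1800-bp genes — small enough to
analyse in seconds, large enough that every amino-acid class accumulates
hundreds of counts. With `intergenic_phase_strength` > 0 the intergenic
background gets a 10-bp periodic base composition (A/T enriched at phase 0,
G/C at phase 5, anchored to absolute coordinates); 0.6 gives a strong but
not caricatural modulation. `planted_phased_map` then places dyads every
180 bp, snapped to the absolute 10-bp grid (plus optional jitter) in the
phased regions and at uniform-random phase elsewhere, with a chosen
fraction of records given sub-threshold score/noise. Planting phasing only
outside genes reproduces the below-diagonal multiplexing signature as
ground truth; planting nowhere gives the null.

What the generator does *not* emulate: real codon-usage bias, nucleosome
density correlations, mapping-chemistry biases around the dyad, introns at
realistic rates, or the actual mechanical texture of evolved genomes.
Passing the recovery tests shows the *analysis chain* is correct and
sensitive, not that any particular organism multiplexes.

## Problem sizes in the tests and acceptance script

The test suite and `scripts/acceptance.py` run the pipelines at reduced
scale, chosen for statistical adequacy: ≥10⁵ recorded MMC sequences for the
positioning rules (the profiles' binomial error is then ≪ the signal), 100
(tests) / 60 (script) random coding sequences for the sMMC average with a
bootstrap over genes, 10⁶ moves for the exact-Boltzmann comparison, 3-footprint
lattices for the enumeration oracle, and 2×60 kb synthetic genomes
(~600 dyads) for the multiplexing contrast.

## Known limitations

* Nearest-neighbour (dinucleotide) sequence dependence only; no
  electrostatics, solvent, histone tails, unwrapping or twist defects.
* The constraint fixture is an idealized superhelix, not a
  crystal-structure derivation; absolute energies (and hence meaningful μ
  values) are parametrization- and fixture-dependent.
* The stiffness entries are transcribed summaries, not an authoritative
  copy of any single published matrix set; conclusions that depend on fine
  quantitative detail of one parametrization should re-derive the table.
* Landscape estimates are Monte Carlo means, not free energies; at very low
  effective temperature they approximate the constrained energy minimum.
* Only the standard genetic code ships (the tables are built from the
  standard-code object and could be swapped, but no alternative is wired
  through).
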