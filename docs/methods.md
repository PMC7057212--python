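# Methods

## Phase-set model

A partial molecular-replacement solution is represented by its phase set:
Miller indices **h**, amplitudes *F*(**h**) ≥ 0, figures of merit
*m*(**h**) ∈ [0, 1] and phases φ(**h**) in degrees. In the intended use all
solutions against one data set share the observed amplitudes and differ only
in phases and figures of merit; the merge step therefore treats divergent
amplitude arrays as an error. Reflection lists use one fixed uniqueness
convention — the lexicographically maximal index over all rotation images
and Friedel mates — and systematically absent reflections are removed.
Comparing sets indexed under different conventions raises an error rather
than remapping silently.

Phases computed from coordinates use direct structure-factor summation over
the space-group operators with point atoms, unit scattering weights and no
thermal motion. Every algorithm in the package depends on phase
relationships rather than amplitude realism, so form factors and B-factors
would add cost without changing any tested behaviour.

## Similarity metrics

For two sets with phase difference Δφ(**h**) (wrapped to [0°, 180°]):

* wMPD = Σ *w* |Δφ| / Σ *w*, with reflection weight *w* = *m*₁*m*₂*F*²
  (implemented as *m*₁*m*₂*F*₁*F*₂, identical when amplitudes are shared).
  The *F*² factor is the standard Sim/Lunin-style weighting; it makes the
  uncorrelated limit 90° independent of the amplitude distribution.
* mapCC = Σ *m*₁*m*₂*F*₁*F*₂ cos Δφ / √(Σ(*m*₁*F*)² Σ(*m*₂*F*)²). This
  reciprocal-space expression equals the real-space correlation coefficient
  of the two figure-of-merit-weighted Fourier syntheses (means removed,
  F000 excluded); the equality is verified against a gridded-map oracle in
  the test suite.

wMPD computed against the true phases is referred to as the wMPE; sets with
wMPE < 80° are flagged nonrandom.

## Allowed origin shifts

A translation **d** of the whole structure preserves the space-group
symmetry — and hence every amplitude — exactly when (R − I)**d** is a
lattice translation for every rotation part R of the group, the phases
changing as φ′ = φ − 360°·(**h**·**d**). Axes along which this holds for any
**d** are polar; on the remaining axes only a discrete set survives. The
tables for the eight supported groups (P1, P2₁, C2, P2₁2₁2₁, C222₁, F222,
F23, P6₃) are hard coded on the unit-cell torus, including
centring-equivalent copies for the F-centred groups (these act identically
on allowed reflections, so shift recovery is only defined modulo the
centring translations — the comparison helper `shifts_equivalent` accounts
for this). Each table is re-validated on first load against the normalizer
condition above, and the test suite additionally validates every tabulated
shift by the brute-force amplitude-invariance oracle. Enantiomorph (hand)
alternatives and re-indexing ambiguities are deliberately out of scope: only
pure origin translations are searched.

## Origin-shift search

* **Nonpolar groups** — exhaustive enumeration of the discrete shifts;
  ties broken toward the first shift in canonical (sorted) order.
* **Sparse (polar)** — for each discrete candidate, the polar component is
  seeded from the weighted circular mean of the phase differences on the
  layer of polar index 1 (where the phase difference equals 360°·t plus
  noise), then refined against all reflections by bounded scalar
  minimization of the wMPD within ±0.05 of the seed (tolerance 10⁻⁶
  fractional). In P1 the per-axis layers reduce to the three axial
  reflections, too few to seed from; the dispatcher therefore never selects
  sparse there and a missing layer raises an explicit error.
* **FFT (polar)** — coefficients G(**h**) = w·exp(iΔφ) are accumulated on a
  grid indexed by the polar components of **h** mod N (N = 64 by default, a
  power of two); one inverse FFT evaluates the translation function
  T(**t**) = Re Σ G·exp(2πi **h**·**t**) on the whole polar grid. The
  argmax is polished by coordinate-wise bounded minimization of the wMPD
  within ±1 grid cell per axis.

The automatic rule uses the FFT whenever every axis is polar (P1), and
otherwise the sparse search with an FFT fallback if the seeding layer is
absent. Construction tests recover continuous shifts to better than 0.002
fractional; a dense-grid brute-force search serves as the independent
cross-check of both polar algorithms.

## Merging and referential clustering

Members within the wMPD tolerance of a reference are combined, after
applying their origin shifts, into the weighted circular average
Σ ω·m·exp(iφ) with member weight ω = (tolerance − wMPD)/tolerance and
reference weight 1 — the simplest instantiation of similarity-proportional
weighting; cosine alternatives were rejected for transparency. The combined
figure of merit is the resultant length |Σ ω·m·exp(iφ)| / Σ ω·m, clipped to
[0, 1]: 1 where members agree, 0 where they cancel (e.g. antipodal phases).
Amplitudes are copied from the reference.

Clustering is referential and iterative: cycle 1 compares all candidates to
the raw reference, later cycles to the running average, membership being
re-decided from scratch each cycle; iteration stops at the cycle budget
(three by default) or as soon as membership is stable. The engine processes
the whole input list, removing clustered sets; in sequential-continuation
mode a reference that clusters nothing is set aside as a leftover and the
next list entry is tried.

## Orchestration

Solutions are sorted by their phasing scores (CC, then LLG, scored sets
first; stable order otherwise). Comparison runs at a reduced resolution —
4.0 Å by default, 3.5 Å in P1 where the fully unconstrained origin makes
shift determination more error-prone — and the final clusters are re-merged
with all reflections, the per-member wMPD entering the merge weights being
re-evaluated at the fixed shift against the full data. While the pool is
larger than `minchunk` (2 × cores by default; the threshold value is a
package choice), the comparison loop for each common reference is split
into contiguous chunks over workers and results are aggregated in chunk
order; because admission depends only on the (candidate, reference) pair,
membership is provably independent of the chunking, which the tests confirm
for 1, 2 and 4 cores. The default worker count is the machine's cores minus
one, capped at ten. Random seeds govern only synthetic data, never
clustering decisions.

The two-step protocol clusters within each rotation group at the base
tolerance, then clusters the merged round-1 sets across groups at 87°.
Only round-1 clusters enter round 2 (leftover singletons stay leftovers);
this is one of two defensible readings of the protocol and is the
documented choice. Solutions from fragments of different structural type
carry complementary information and sit at mutual wMPDs approaching the 90°
random floor; the tests reproduce the regime in which disjoint small
fragments of one structure combine at an 83° tolerance but not at 60°.

## Synthetic landscapes

The generator emulates the statistical structure of fragment-phasing
landscapes from a toy point-atom crystal (atoms rejection-sampled to keep
all symmetry images ≥ 0.5 Å apart; default cells sized so that a few
hundred unique reflections survive the 4.0 Å comparison cutoff — with far
fewer reflections, the wMPD of unrelated sets develops a heavy tail below
its 90° floor that small toy cells would otherwise exaggerate):

* **correct** solutions share one randomly chosen core subset of the
  structure (default fraction 0.5), with per-solution Gaussian coordinate
  jitter (default 0.1 Å), wrapped-Gaussian phase noise (default 40°) and a
  random allowed origin shift — emulating overlapping fragments that share
  a consensus core;
* **wrong** solutions are freshly drawn unrelated structures of the same
  size, reproducing the ≈90° wMPE noise floor without modelling the
  search program that produced them;
* every solution carries the truth amplitudes, a Luzzati-style figure of
  merit exp(−½(2πσ_eff/d)²) with σ_eff composed from the coordinate noise,
  incompleteness and phase noise, and CC/LLG-like scores drawn so that
  correct solutions are stochastically higher with overlap between the
  populations.

What passing tests on these landscapes do show: correct-family recovery,
core-count invariance, resolution-cutoff robustness, and the merged set
beating its best member. What they do not show: behaviour under correlated
wrong solutions (real landscapes contain consistent *wrong* families,
because fragment placements are not generated independently), realistic
amplitude errors, or solvent effects; conclusions about real data rest on
the method, not on these emulations.

## Numerical choices and limitations

* Phases are stored in degrees in [0, 360); the shift convention is
  φ′ = φ − 360°·(**h**·**t**) for a structure moved by +**t**.
* Shift-search ties are broken toward the earlier candidate; merge weights
  are floored at 10⁻⁶ so a member admitted exactly at the tolerance still
  contributes formally.
* The shift-recovery tests use a 5° probe noise: the statistical
  displacement of the wMPD optimum scales with the noise over the root of
  the reflection count, and at this level it stays well below the 0.002
  fractional band being checked, so the tests measure search precision
  rather than the noise floor. Robustness of shift *selection* under heavy
  noise (30°) is checked separately against an enumeration oracle.
* Test and acceptance problem sizes (toy cells of 20–40 Å, 20–45 atoms,
  landscapes of 16–30 solutions, d_min 2.5 Å) are chosen so the full suite
  exercises every code path in about a minute on one core.
* The eigen-embedding of the CC matrix clips negative eigenvalues to zero;
  it provides starting coordinates whose dot products approximate the CCs
  and is not a substitute for a full least-squares vector refinement.
* Coverage is limited to the eight space groups listed; non-standard
  settings, anomalous data, MTZ/CIF reflection formats and density
  modification are out of scope.
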