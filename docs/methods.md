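# Methods

This document defines the algorithms implemented in `xltrigger`, the
numerical conventions they rely on, and the guarantees (and non-guarantees)
of the synthetic benchmark generator. Everything stated here is either a
definition or a property checked by the test suite or by
`scripts/acceptance.py`.

## Chemistry model

A cleavable cross-linker is described by a set of named stubs (label,
elemental composition, monoisotopic mass), a set of active doublet pairs
(light stub, heavy stub), and the full linker mass added to a residue pair.
Masses are computed from elemental compositions using pyteomics' NIST atomic
mass table; one shared table is used everywhere so that all derived masses
are internally consistent.

The DSSO preset:

| stub | composition | mass (Da) |
|---|---|---|
| A (alkene) | C3H2O | 54.01057 |
| T (thiol) | C3H2OS | 85.98264 |
| S (sulfenic acid) | C3H4O2S | 103.99320 |

Identities maintained by construction and asserted against an independent
atomic-mass table in the tests: `mass(T) − mass(A)` equals one sulfur atom
(31.97207 Da), and the full linker mass equals `mass(A) + mass(S)` =
158.00377 Da. Only the (A, T) pair is active by default; the sulfenic-acid
form usually loses water in the collision cell, so the A/S doublet is rarely
observable and is left inactive (it can be enabled in a linker YAML). A DSBU
preset is included as a second worked configuration.

Constants: proton mass 1.007276466 Da; averaged isotope gap 1.00335 Da
(the averagine C12/C13-dominated spacing; using a single averaged gap
rather than element-resolved spacings is an approximation that holds well
below the ppm tolerances used here for peptides under ~5 kDa).

## Step 1 — deconvolution

Input: a centroided MS² spectrum (m/z-sorted peaks). For every charge
hypothesis z from `max_charge` down to 1 and every starting peak, a ladder
is walked left to right: the next member is the peak closest to
`last + 1.00335/z` within `cluster_tol_ppm` (default 7 ppm). A coarse
unimodality constraint — member intensities may rise then fall at most once
— stops a ladder from running through an unrelated, more intense species.
`max_charge` defaults to the precursor charge when known (a fragment cannot
plausibly carry more charge than its precursor), else 4.

All multi-member ladders for all charges are candidates; conflicts over
shared peaks are resolved by a deterministic greedy acceptance in the order

1. fewest *straddled half-gap peaks* — a ladder at charge z whose
   consecutive members straddle an in-tolerance peak at the half-step
   position is really a 2z envelope misread at half the charge (the classic
   charge-halving signature), so such candidates rank last;
2. longest envelope — a long ladder is exponentially stronger evidence than
   a short one, so a 2-member spurious chain at some other charge cannot
   cannibalize a ≥3-member genuine envelope;
3. highest charge, then lowest monoisotopic m/z, as final deterministic
   tie-breaks.

When an accepted envelope has already claimed a tail member of a later
candidate, the candidate's maximal unclaimed prefix is accepted instead
(if it still has ≥ 2 members): the prefix keeps the monoisotopic peak and
remains a valid envelope. Both refinements were adopted after constructed
counterexamples showed that simpler orderings (charge-first or
length-first alone) mis-assign envelopes when unrelated species happen to
sit one isotope gap apart at some charge; the stress test in the suite
covers these cases.

Peaks belonging to no accepted envelope are emitted as singletons with
charge 0 (unknown). They participate in intensity ranking but are excluded
from doublet matching — a deliberate precision-over-recall choice: a
singleton's charge cannot be verified, and a wrong charge would corrupt the
second-peptide mass.

Ranking: envelopes are ranked 1..n by their **maximum member peak
intensity** (not the summed intensity), ties broken toward lower
monoisotopic m/z. Rank-by-tallest-member mirrors what an instrument's
real-time view of the top-N peak list would see.

Intensity is conserved exactly: every source peak is assigned to exactly
one output peak (asserted as a property-based invariant).

## Step 2 — doublet matching

For every active doublet pair with mass difference Δ, and every
deconvoluted peak with known charge z, a match is recorded when another
peak of the *same charge* lies within `ms2_tol_ppm` (default 5 ppm) of
`light_mz + Δ/z`. The tolerance is relative to the theoretical heavy
position. Matching uses a binary search over the m/z-sorted peak list; the
test suite asserts exact agreement with an all-pairs brute force on
thousands of random spectra, so the indexing is an optimization with no
semantic content.

5 ppm is an MS² mass-accuracy figure typical of Orbitrap instruments;
`cluster_tol_ppm` is looser (7 ppm) because envelope spacings compound two
peak errors.

## Step 3 — intensity-rank filter

A match survives if `min(rank_light, rank_heavy) ≤ rank_cutoff` (default
20): at least one member must be among the top-20 envelopes. The `min`
(rather than `max`) convention deliberately tolerates one weak member —
stub intensities are often asymmetric. The filter is idempotent and
monotone in the cutoff (both asserted).

## Step 4 — second-peptide mass filter

For a doublet with light-stub peptide mass
`pep = (light_mz − proton)·z − mass(light stub)` and a known MS² precursor
(neutral mass M), the mass the partner peptide must have is

```
second = M − pep − full_linker_mass
```

Computing it from the heavy member gives the identical value (asserted).
Matches with `second ≥ second_peptide_min_mass` (default 500 Da, boundary
**inclusive**) survive. 500 Da is roughly the smallest tryptic peptide
worth an MS³ scan. For a linear peptide carrying a hydrolyzed linker, the
planted doublet is genuine but `second` evaluates to ~18 Da (water), so
this filter is what suppresses that class. If the precursor charge is
unknown the filter cannot be evaluated; the match is kept and the decision
is flagged (`second_peptide_filter_applied = False`) — a conservative
"trigger when unsure" policy, as a missed cross-link costs more than a
wasted MS³ scan.

## Target selection

Surviving matches are expanded into candidate targets (both members of each
doublet — both cross-linked peptides should be fragmented), ordered by
(doublet rank = min of member ranks, then higher summed envelope intensity,
then lower m/z), deduplicated at 1 ppm + equal charge, and truncated to
`cap` targets (default 4: two doublets' worth, matching typical
MS³-per-MS² instrument budgets).

## Evaluation

* **Doublet presence**: for each cross-link spectrum match (CSM), whether
  the surviving matches of the pipeline cover the stub-bearing species of
  peptide 1 / peptide 2 (matched at 15 ppm against theoretical
  peptide+stub m/z over plausible charges).
* **Correctly triggered**: fraction of MS³ scans whose precursor m/z lies
  within 20 ppm of a stub-bearing species of its parent scan's identified
  CSM. MS³ scans whose parent has no CSM are counted separately as orphans.
* **MS³-per-MS² rates** per scan class, with percentile-bootstrap 95%
  confidence intervals (10,000 resamples, caller-seeded NumPy generator).
  Percentile bootstrap was chosen over normal approximation because the
  per-scan counts are small integers with highly non-normal distributions.
* CSM prefilters: minimum peptide length 5; optionally, removal of
  sequence-consecutive peptide pairs (likely mis-cleaved linears) when
  protein-position columns are present.

## Synthetic generator

Each scan draws a class (cross-linked / linear / linker-modified linear),
random tryptic peptides (length 7–14, K/R C-terminus, internal K link
site, mass ≥ 600 Da), a precursor charge (3–5), and species:

* b/y backbone fragments at z = 1 (intensities U(1e3, 3e4)),
* for cross-linked scans, peptide+A and peptide+T for both peptides at a
  doublet charge in {1, 2} (intensities U(5e4, 1e5)),
* for linker-modified scans, the same doublet for one peptide with the
  precursor carrying the hydrolyzed linker (full mass + water), so the
  doublet is real but the second-peptide mass is ~18 Da,
* optional uniform-m/z noise peaks (intensity capped at the median
  backbone intensity), optional decoy *near*-doublet pairs offset by
  0.5–18 ppm (for tolerance sweeps), optional suppression of the heavy
  member, optional bounded uniform ±jitter ppm per peak.

Isotope envelopes (depth 3–4, geometric decay 0.6) are expanded around each
species.

**Ground-truth guarantee.** The generator *rejects and redraws* a scan's
species when any of the following would hold, so that on clean (unjittered)
data the planted annotation is the unique reading:

* two cross-species envelope positions (including one ladder step beyond
  the planted depth) within a 25 ppm guard band,
* a non-planted same-charge pair within 30 ppm of a doublet spacing Δ/z,
* a noise peak within 25 ppm of any planted position.

These guard bands were fixed at design time as comfortable multiples of the
matching tolerances (5/7 ppm). They are what makes "trigger rate exactly
1.0 / 0.0" a well-defined target rather than a statistical statement. The
guard does **not** exclude cross-species *isotope-gap* coincidences at
foreign charges (one species sitting 1.00335/z from another species' member
for some unrelated z); the deconvolution resolution order above was
hardened to be robust to exactly those, and a multi-seed stress test covers
it.

**Jitter vs. cluster tolerance.** With per-peak jitter bounded at ±j ppm,
the spacing error between two envelope members reaches 2j. Jittered
benchmarks therefore use `cluster_tol = max(7, 3·j)` ppm; this rule is
applied by `sweep_tolerance` and stated here because silently keeping the
7 ppm default would make envelope recovery fail for reasons unrelated to
the doublet tolerance under study.

What the generator does **not** emulate: isotope-envelope shapes beyond
geometric decay (no averagine fitting is needed since only mono m/z,
charge and rank matter downstream), overlapping co-isolated precursors,
electronic noise models, retention-time structure, or real instrument
top-N dynamics. Benchmark sizes used by the tests and the acceptance
script (60–200 scans per condition, 1000 random spectra for the
brute-force comparison) are this package's own choices, sized to keep the
full suite under ~10 s while making the exact-rate assertions meaningful.

## Boundary and determinism conventions

* All ppm windows are inclusive (`≤`); the second-peptide minimum mass is
  inclusive (`≥ 500` kept).
* Every ordering has a total, documented tie-break (rank ties → lower m/z;
  target ties → rank, summed intensity, m/z; envelope conflicts → the
  four-key order above), so all outputs are byte-deterministic for a given
  input and seed. The generator is byte-identical for equal seeds
  (asserted).
* Derived seeds are kept below 2³¹ for portability.

## Open decisions and limitations

* The A/S (alkene / sulfenic acid) doublet is modeled but inactive by
  default; enabling it doubles the matcher's search pairs and would need
  its own tolerance validation.
* Charge-0 singletons never match; a future refinement could try charge
  hypotheses on singletons at the cost of precision.
* The deconvolution conflict resolution is a greedy heuristic with a
  charge-halving guard, not a global optimization; pathological spectra
  could still be mis-assigned, though the multi-seed stress tests found no
  such case on generator output.
* `decide()` only accepts MS² spectra (MS³ input raises), and the pipeline
  assumes centroided data; no profile-mode peak picking is included.
* Real acquisition would apply this logic under a time budget per duty
  cycle; scheduling/latency is out of scope — the package computes the
  decision, not the instrument control.
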