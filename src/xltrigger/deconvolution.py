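"""Isotope-envelope detection, deisotoping and intensity ranking (step 1).

The envelope model is a greedy spacing-ladder walk: starting from each peak,
members are chained at the averaged isotope gap 1.00335/z within a ppm
tolerance, for each charge hypothesis z.  A coarse unimodality constraint
(member intensities rise then fall at most once) stops a ladder from running
through an unrelated, more intense species.  Competing hypotheses over shared
peaks are resolved deterministically: fewest straddled half-gap peaks first
(a ladder at charge z that skips over a peak sitting at the half step is
really a 2z envelope), then longest envelope, then highest charge, then
lowest monoisotopic m/z.  No averagine fitting is attempted —
for doublet detection only the monoisotopic m/z, charge and intensity rank
matter.

Isolated peaks are retained as singleton peaks with charge 0 (unknown); they
take part in intensity ranking but are excluded from doublet matching.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace

from .chem import ISOTOPE_GAP
from .spectra import Spectrum

DEFAULT_CLUSTER_TOL_PPM = 7.0
DEFAULT_MAX_CHARGE = 4
DEFAULT_MIN_ENVELOPE_SIZE = 2


@dataclass(frozen=True)
class DeconvolutedPeak:
    """A deisotoped peak: monoisotopic m/z, charge and envelope intensities.

    ``charge`` 0 marks a singleton whose charge could not be inferred.
    ``rank`` is 1 for the most intense envelope (by its maximum member peak).
    """

    mono_mz: float
    charge: int
    summed_intensity: float
    max_member_intensity: float
    member_indices: tuple[int, ...]
    rank: int = 0


@dataclass(frozen=True)
class Envelope:
    """A candidate isotope cluster: member peak indices + charge hypothesis."""

    charge: int
    member_indices: tuple[int, ...]
    mono_mz: float


def detect_isotope_clusters(
    spectrum: Spectrum,
    max_charge: int = DEFAULT_MAX_CHARGE,
    cluster_tol_ppm: float = DEFAULT_CLUSTER_TOL_PPM,
) -> list[Envelope]:
    """Enumerate candidate isotope clusters for every charge 1..max_charge.

    Each candidate is a maximal ladder of peaks spaced by 1.00335/z within
    ``cluster_tol_ppm`` of the expected position, walked left to right with
    the unimodal-intensity constraint.  Peaks that start no multi-member
    ladder for any charge are emitted as singleton charge-0 candidates.
    Overlap between candidates is allowed here; :func:`deconvolute` resolves
    it.
    """
    peaks = spectrum.peaks
    mzs = [p.mz for p in peaks]
    n = len(peaks)
    envelopes: list[Envelope] = []
    in_multimember: set[int] = set()

    for z in range(max_charge, 0, -1):
        step = ISOTOPE_GAP / z
        for start in range(n):
            members = [start]
            direction_down = False  # becomes True once intensity has fallen
            while True:
                last = members[-1]
                expected = mzs[last] + step
                tol = expected * cluster_tol_ppm * 1e-6
                lo = bisect.bisect_left(mzs, expected - tol, last + 1)
                hi = bisect.bisect_right(mzs, expected + tol, last + 1)
                if lo >= hi:
                    break
                # closest peak to the expected position wins
                nxt = min(range(lo, hi), key=lambda i: abs(mzs[i] - expected))
                if peaks[nxt].intensity > peaks[last].intensity:
                    if direction_down:
                        break  # second rise: likely a different species
                else:
                    direction_down = True
                members.append(nxt)
            if len(members) >= 2:
                # suffix ladders (starting at an interior member) are also
                # emitted; deconvolute()'s longest-first greedy acceptance
                # discards them once the full ladder claims their peaks
                envelopes.append(
                    Envelope(charge=z, member_indices=tuple(members), mono_mz=mzs[start])
                )
                in_multimember.update(members)

    for i in range(n):
        if i not in in_multimember:
            envelopes.append(Envelope(charge=0, member_indices=(i,), mono_mz=mzs[i]))
    return envelopes


def deconvolute(
    spectrum: Spectrum,
    cluster_tol_ppm: float = DEFAULT_CLUSTER_TOL_PPM,
    max_charge: int | None = None,
    min_envelope_size: int = DEFAULT_MIN_ENVELOPE_SIZE,
) -> list[DeconvolutedPeak]:
    """Deisotope a spectrum into monoisotopic peaks with charges and ranks.

    ``max_charge`` defaults to the precursor charge when known (fragments
    cannot plausibly exceed it), else 4.  Each source peak is assigned to at
    most one emitted peak; conflicts are resolved by accepting envelopes in
    (fewest straddled half-gap peaks, longest, highest charge, lowest mono
    m/z) order.  Unassigned peaks are
    emitted as charge-0 singletons.  The returned list is sorted by mono_mz
    and carries intensity ranks (see :func:`assign_intensity_ranks`).
    """
    if max_charge is None:
        max_charge = (
            spectrum.precursor.charge
            if spectrum.precursor.charge > 0
            else DEFAULT_MAX_CHARGE
        )
    candidates = [
        e
        for e in detect_isotope_clusters(spectrum, max_charge, cluster_tol_ppm)
        if len(e.member_indices) >= max(min_envelope_size, 2)
    ]
    # a ladder at charge z that straddles an in-tolerance peak at the half
    # step is really a 2z envelope misread at half the charge; such
    # candidates must not outrank the clean higher-charge interpretation,
    # and among clean candidates a short spurious ladder at a higher charge
    # must not steal members from a long genuine envelope
    mzs = [p.mz for p in spectrum.peaks]

    def straddled(env: Envelope) -> int:
        half = ISOTOPE_GAP / (2 * env.charge)
        count = 0
        for a in env.member_indices[:-1]:
            expected = mzs[a] + half
            tol = expected * cluster_tol_ppm * 1e-6
            lo = bisect.bisect_left(mzs, expected - tol)
            if lo < len(mzs) and mzs[lo] <= expected + tol:
                count += 1
        return count

    candidates.sort(
        key=lambda e: (straddled(e), -len(e.member_indices), -e.charge, e.mono_mz)
    )

    used: set[int] = set()
    accepted: list[Envelope] = []
    for env in candidates:
        # a previously accepted envelope may have claimed a tail member of
        # this ladder; the unclaimed prefix keeps the monoisotopic peak and
        # remains a valid (shorter) envelope
        prefix: list[int] = []
        for i in env.member_indices:
            if i in used:
                break
            prefix.append(i)
        if len(prefix) < max(min_envelope_size, 2):
            continue
        accepted.append(
            Envelope(charge=env.charge, member_indices=tuple(prefix), mono_mz=env.mono_mz)
        )
        used.update(prefix)

    peaks = spectrum.peaks
    out: list[DeconvolutedPeak] = []
    for env in accepted:
        intens = [peaks[i].intensity for i in env.member_indices]
        out.append(
            DeconvolutedPeak(
                mono_mz=env.mono_mz,
                charge=env.charge,
                summed_intensity=sum(intens),
                max_member_intensity=max(intens),
                member_indices=env.member_indices,
            )
        )
    for i, p in enumerate(peaks):
        if i not in used:
            out.append(
                DeconvolutedPeak(
                    mono_mz=p.mz,
                    charge=0,
                    summed_intensity=p.intensity,
                    max_member_intensity=p.intensity,
                    member_indices=(i,),
                )
            )
    out.sort(key=lambda p: p.mono_mz)
    return assign_intensity_ranks(out)


def assign_intensity_ranks(peaks: list[DeconvolutedPeak]) -> list[DeconvolutedPeak]:
    """Assign contiguous ranks 1..n by descending maximum member intensity.

    Ties break toward the lower monoisotopic m/z.  This is the "deisotoped
    max rank": an envelope ranks by its tallest member peak, not its summed
    intensity.
    """
    order = sorted(
        range(len(peaks)), key=lambda i: (-peaks[i].max_member_intensity, peaks[i].mono_mz)
    )
    ranked = list(peaks)
    for rank0, idx in enumerate(order):
        ranked[idx] = replace(peaks[idx], rank=rank0 + 1)
    return ranked
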