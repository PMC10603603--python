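"""Stub-doublet matching and the MS3 trigger decision (steps 2-4).

After deisotoping, a cross-linked peptide that lost its partner through
in-source linker cleavage appears twice: once with the light stub and once
with the heavy stub, separated by exactly delta_mass/z.  The engine

1. matches every deconvoluted peak against every charge-matching peak at the
   theoretical partner position (``mz + delta/z``) within a ppm tolerance,
2. keeps a doublet when at least one member ranks within the top
   ``rank_cutoff`` peaks by intensity (noise suppression),
3. keeps a doublet only when the precursor leaves at least
   ``second_peptide_min_mass`` Da for the partner peptide — removing
   linker-modified linear peptides and random matches,
4. emits both doublet members as MS3 targets, deduplicated and capped.

Defaults are 5 ppm, rank 20, 500 Da, cap 4 with DSSO stubs A/T.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace

from .chem import PROTON_MASS, CrosslinkerDefinition, DoubletPair, dsso
from .deconvolution import DeconvolutedPeak, deconvolute
from .spectra import PrecursorInfo, Spectrum


@dataclass(frozen=True)
class TriggerConfig:
    """Tunable parameters of the trigger decision."""

    ms2_tol_ppm: float = 5.0
    rank_cutoff: int = 20
    cap: int = 4
    second_peptide_min_mass: float = 500.0
    cluster_tol_ppm: float = 7.0

    def __post_init__(self) -> None:
        for name in ("ms2_tol_ppm", "rank_cutoff", "cap", "second_peptide_min_mass", "cluster_tol_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class DoubletMatch:
    """A light/heavy deconvoluted-peak pair consistent with a stub doublet."""

    light_peak: DeconvolutedPeak
    heavy_peak: DeconvolutedPeak
    pair: DoubletPair
    charge: int
    observed_delta_ppm: float  # deviation of heavy m/z from theoretical
    second_peptide_mass: float | None = None
    second_peptide_unfiltered: bool = False  # precursor charge unknown

    @property
    def doublet_rank(self) -> int:
        return min(self.light_peak.rank, self.heavy_peak.rank)

    @property
    def peptide_neutral_mass_light(self) -> float:
        """Stub-free neutral mass of the doublet peptide, from the light member."""
        return (self.light_peak.mono_mz - PROTON_MASS) * self.charge - self.pair.light.mass


@dataclass(frozen=True)
class MS3Target:
    mz: float
    charge: int
    source: DoubletMatch


@dataclass(frozen=True)
class MS3Decision:
    scan_id: str
    targets: tuple[MS3Target, ...]
    second_peptide_filter_applied: bool = True

    @property
    def trigger(self) -> bool:
        return len(self.targets) > 0


def match_doublets(
    peaks: list[DeconvolutedPeak],
    xl: CrosslinkerDefinition,
    tol_ppm: float = 5.0,
) -> list[DoubletMatch]:
    """Match stub doublets among deconvoluted peaks by delta mass and charge.

    For each peak p with known charge z and each active doublet pair, the
    theoretical partner sits at ``p.mono_mz + delta_mass/z``; every peak of
    the same charge within ``tol_ppm`` (relative to the theoretical partner
    m/z) yields one match.  A peak may take part in several matches.
    """
    charged = sorted((p for p in peaks if p.charge >= 1), key=lambda p: p.mono_mz)
    mzs = [p.mono_mz for p in charged]
    matches: list[DoubletMatch] = []
    for light in charged:
        z = light.charge
        for pair in xl.doublet_pairs:
            theo = light.mono_mz + pair.delta_mass / z
            tol = theo * tol_ppm * 1e-6
            lo = bisect.bisect_left(mzs, theo - tol)
            hi = bisect.bisect_right(mzs, theo + tol)
            for j in range(lo, hi):
                heavy = charged[j]
                if heavy.charge != z:
                    continue
                matches.append(
                    DoubletMatch(
                        light_peak=light,
                        heavy_peak=heavy,
                        pair=pair,
                        charge=z,
                        observed_delta_ppm=(heavy.mono_mz - theo) / theo * 1e6,
                    )
                )
    return matches


def apply_rank_filter(matches: list[DoubletMatch], rank_cutoff: int = 20) -> list[DoubletMatch]:
    """Keep matches with at least one member in the top ``rank_cutoff`` ranks.

    I.e. ``min(rank_light, rank_heavy) <= rank_cutoff``; the boundary rank is
    kept.
    """
    return [m for m in matches if m.doublet_rank <= rank_cutoff]


def second_peptide_mass(
    match: DoubletMatch,
    precursor: PrecursorInfo,
    xl: CrosslinkerDefinition,
) -> float | None:
    """Neutral mass left for the partner peptide, or None if precursor charge
    is unknown.

    The doublet peptide (stub-free) and the intact linker are subtracted from
    the precursor neutral mass; what remains is the second peptide.  Computing
    from the heavy member gives the identical value since the two members
    differ by exactly the stub mass difference.
    """
    neutral = precursor.neutral_mass
    if neutral is None:
        return None
    return neutral - match.peptide_neutral_mass_light - xl.full_mass


def apply_second_peptide_filter(
    matches: list[DoubletMatch],
    precursor: PrecursorInfo,
    xl: CrosslinkerDefinition,
    min_mass: float = 500.0,
) -> list[DoubletMatch]:
    """Keep matches whose second-peptide mass is >= ``min_mass`` (boundary kept).

    When the precursor charge is unknown the mass is undefined; such matches
    are kept and flagged ``second_peptide_unfiltered``.
    """
    out = []
    for m in matches:
        spm = second_peptide_mass(m, precursor, xl)
        if spm is None:
            out.append(replace(m, second_peptide_mass=None, second_peptide_unfiltered=True))
        elif spm >= min_mass:
            out.append(replace(m, second_peptide_mass=spm))
    return out


def select_targets(
    matches: list[DoubletMatch],
    cap: int = 4,
    scan_id: str = "",
    second_peptide_filter_applied: bool = True,
) -> MS3Decision:
    """Turn surviving doublets into a capped, ordered MS3 target list.

    Both members of every doublet are candidates (ideally two MS3 scans per
    cross-link, one per peptide).  Candidates are deduplicated by (m/z within
    1 ppm, charge), ordered by doublet rank, then summed intensity
    (descending), then m/z, and truncated to ``cap``.
    """
    candidates: list[MS3Target] = []
    for m in matches:
        for peak in (m.light_peak, m.heavy_peak):
            candidates.append(MS3Target(mz=peak.mono_mz, charge=m.charge, source=m))

    def sort_key(t: MS3Target):
        peak = t.source.light_peak if t.mz == t.source.light_peak.mono_mz else t.source.heavy_peak
        return (t.source.doublet_rank, -peak.summed_intensity, t.mz)

    candidates.sort(key=sort_key)
    selected: list[MS3Target] = []
    for cand in candidates:
        dup = any(
            cand.charge == s.charge and abs(cand.mz - s.mz) <= s.mz * 1e-6
            for s in selected
        )
        if not dup:
            selected.append(cand)
        if len(selected) >= cap:
            break
    return MS3Decision(
        scan_id=scan_id,
        targets=tuple(selected),
        second_peptide_filter_applied=second_peptide_filter_applied,
    )


def decide(
    spectrum: Spectrum,
    xl: CrosslinkerDefinition | None = None,
    config: TriggerConfig | None = None,
) -> MS3Decision:
    """Run the full four-step trigger pipeline on one MS2 spectrum."""
    if spectrum.ms_level != 2:
        raise ValueError("trigger decisions apply to MS2 spectra only")
    xl = xl if xl is not None else dsso()
    config = config if config is not None else TriggerConfig()

    peaks = deconvolute(spectrum, cluster_tol_ppm=config.cluster_tol_ppm)
    matches = match_doublets(peaks, xl, config.ms2_tol_ppm)
    matches = apply_rank_filter(matches, config.rank_cutoff)
    filtered_applied = spectrum.precursor.charge > 0
    matches = apply_second_peptide_filter(
        matches, spectrum.precursor, xl, config.second_peptide_min_mass
    )
    return select_targets(
        matches,
        cap=config.cap,
        scan_id=spectrum.scan_id,
        second_peptide_filter_applied=filtered_applied,
    )
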