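"""Peptide and fragment mass arithmetic and spectrum annotation.

Monoisotopic masses only (high-resolution Orbitrap context), taken from the
same atomic-mass table as the cross-linker chemistry (pyteomics' NIST table).
The annotator generates b/y series and, for fragments spanning the
cross-link site, the stub-shifted variants (A/S/T for DSSO), plus the intact
peptide+stub species that the doublet engine targets for MS3.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from pyteomics import mass as _pmass

from .chem import PROTON_MASS, WATER_MASS, CrosslinkerDefinition, Stub
from .spectra import Spectrum

# residue (i.e. water-free) monoisotopic masses of the 20 canonical amino acids
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}


def peptide_neutral_mass(
    sequence: str, modifications: tuple[tuple[int, float], ...] = ()
) -> float:
    """Monoisotopic neutral mass of a peptide with positional mass deltas.

    ``modifications`` are (1-based position, delta Da) pairs; positions are
    not validated beyond the sequence bounds.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER_MASS
    for aa in sequence:
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
    for pos, delta in modifications:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside sequence")
        total += delta
    return total


@dataclass(frozen=True)
class PeptideIon:
    """A peptide with optional modifications, at a given charge."""

    sequence: str
    modifications: tuple[tuple[int, float], ...] = ()
    charge: int = 1

    @property
    def neutral_mass(self) -> float:
        return peptide_neutral_mass(self.sequence, self.modifications)

    @property
    def mz(self) -> float:
        return (self.neutral_mass + self.charge * PROTON_MASS) / self.charge


def mz_from_neutral(neutral: float, charge: int) -> float:
    return (neutral + charge * PROTON_MASS) / charge


def fragment_mzs(
    peptide: PeptideIon,
    series: str = "by",
    max_charge: int = 1,
    stub_on_site: tuple[int, Stub] | None = None,
) -> list[tuple[str, int, float]]:
    """Theoretical b/y fragment m/z values, optionally stub-shifted.

    Returns (label, charge, m/z) triples.  ``series`` is any subset of "by".
    With ``stub_on_site`` = (1-based link position, stub), fragments that
    contain the link site carry the stub mass and the label gains a
    ``+<stub>`` suffix.  b_n (the full peptide minus water) and y_n are
    omitted/included per the usual convention: b runs 1..n-1, y runs 1..n-1.
    """
    seq = peptide.sequence
    n = len(seq)
    if stub_on_site is not None:
        pos, stub = stub_on_site
        if not 1 <= pos <= n:
            raise ValueError(f"stub position {pos} outside sequence of length {n}")
    mods_by_pos: dict[int, float] = {}
    for p, delta in peptide.modifications:
        mods_by_pos[p] = mods_by_pos.get(p, 0.0) + delta

    # prefix residue-mass sums (with fixed modifications folded in)
    prefix = [0.0]
    for i, aa in enumerate(seq, start=1):
        prefix.append(prefix[-1] + RESIDUE_MASSES[aa] + mods_by_pos.get(i, 0.0))

    out: list[tuple[str, int, float]] = []
    for i in range(1, n):  # cleavage between residue i and i+1
        for kind in series:
            if kind == "b":
                neutral = prefix[i]
                covers = stub_on_site is not None and stub_on_site[0] <= i
                label = f"b{i}"
            elif kind == "y":
                neutral = prefix[n] - prefix[i] + WATER_MASS
                covers = stub_on_site is not None and stub_on_site[0] > i
                label = f"y{n - i}"
            else:
                raise ValueError(f"unknown series {kind!r}")
            if covers:
                neutral += stub_on_site[1].mass
                label += f"+{stub_on_site[1].label}"
            for z in range(1, max_charge + 1):
                out.append((label, z, mz_from_neutral(neutral, z)))
    return out


@dataclass(frozen=True)
class FragmentAnnotation:
    peak_index: int
    ion: str
    charge: int
    theo_mz: float
    error_ppm: float


def _theoretical_ions(
    peptides: list[tuple[PeptideIon, int | None]],
    xl: CrosslinkerDefinition,
    max_fragment_charge: int,
) -> list[tuple[str, int, float]]:
    """All theoretical (label, z, m/z) for a CSM: b/y series, stub-shifted
    variants for every stub, and intact peptide+stub species."""
    ions: list[tuple[str, int, float]] = []
    for idx, (pep, link_pos) in enumerate(peptides, start=1):
        tag = f"p{idx}."
        for label, z, mz in fragment_mzs(pep, "by", max_fragment_charge):
            ions.append((tag + label, z, mz))
        if link_pos is not None:
            for stub in xl.stubs:
                for label, z, mz in fragment_mzs(
                    pep, "by", max_fragment_charge, stub_on_site=(link_pos, stub)
                ):
                    if "+" in label:  # only the stub-bearing fragments are new
                        ions.append((tag + label, z, mz))
                # the intact peptide carrying the stub — the MS3 target species
                neutral = pep.neutral_mass + stub.mass
                for z in range(1, max_fragment_charge + 1):
                    ions.append((f"{tag}P+{stub.label}", z, mz_from_neutral(neutral, z)))
    return ions


def annotate(
    spectrum: Spectrum,
    peptides: list[tuple[PeptideIon, int | None]],
    xl: CrosslinkerDefinition,
    tol_ppm: float = 15.0,
    max_fragment_charge: int | None = None,
) -> list[FragmentAnnotation]:
    """Annotate peaks with b/y ions and cross-linker stub fragments.

    ``peptides`` is a list of (peptide, link position or None); for a CSM pass
    both peptides with their link sites, for a linear PSM one peptide with
    link position None.  Every peak within ``tol_ppm`` of a theoretical m/z
    gets an annotation; peaks may carry several.
    """
    if max_fragment_charge is None:
        max_fragment_charge = max(1, spectrum.precursor.charge - 1) if spectrum.precursor.charge > 0 else 2
    ions = _theoretical_ions(peptides, xl, max_fragment_charge)
    ions.sort(key=lambda t: t[2])
    theo_mzs = [t[2] for t in ions]

    out: list[FragmentAnnotation] = []
    for pk_idx, peak in enumerate(spectrum.peaks):
        tol = peak.mz * tol_ppm * 1e-6
        lo = bisect.bisect_left(theo_mzs, peak.mz - tol)
        hi = bisect.bisect_right(theo_mzs, peak.mz + tol)
        for k in range(lo, hi):
            label, z, theo = ions[k]
            out.append(
                FragmentAnnotation(
                    peak_index=pk_idx,
                    ion=label,
                    charge=z,
                    theo_mz=theo,
                    error_ppm=(peak.mz - theo) / theo * 1e6,
                )
            )
    return out


def stub_fragment_mzs(
    peptides: list[tuple[PeptideIon, int | None]],
    xl: CrosslinkerDefinition,
    max_charge: int,
) -> list[tuple[str, int, float]]:
    """The intact peptide+stub species of a CSM (all stubs, charges 1..max)."""
    out = []
    for idx, (pep, link_pos) in enumerate(peptides, start=1):
        if link_pos is None:
            continue
        for stub in xl.stubs:
            neutral = pep.neutral_mass + stub.mass
            for z in range(1, max_charge + 1):
                out.append((f"p{idx}.P+{stub.label}", z, mz_from_neutral(neutral, z)))
    return out
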