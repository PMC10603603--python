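"""Cross-linker chemistry: stub masses, doublet pairs, and shared mass constants.

All mass arithmetic in the package goes through the single atomic-mass table
exposed here (pyteomics' NIST monoisotopic masses), so that doublet matching,
fragment annotation and the synthetic generator can never disagree on a
constant.  The built-in chemistry is DSSO (disuccinimidyl sulfoxide), whose
in-source cleavage leaves an alkene (A), sulfenic-acid (S) or thiol (T)
remnant on each peptide; the A/T pair separated by exactly one sulfur atom
(31.97207 Da) is the doublet signature used for MS3 triggering.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pmass

# One proton; every m/z <-> neutral-mass conversion in the package uses this.
PROTON_MASS = 1.007276466
# Averaged spacing of adjacent isotopologue peaks (Da), the "averagine" gap.
ISOTOPE_GAP = 1.00335
WATER_MASS = _pmass.calculate_mass(formula="H2O")


def composition_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula from the shared table."""
    return float(_pmass.calculate_mass(formula=formula))


@dataclass(frozen=True)
class Stub:
    """A cleavage remnant left on a peptide, e.g. DSSO's alkene stub."""

    label: str
    mass: float  # monoisotopic Da added to the peptide

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"stub {self.label!r} must have positive mass")
        if not self.label:
            raise ValueError("stub label must be non-empty")


@dataclass(frozen=True)
class DoubletPair:
    """Light/heavy stub pair whose fixed mass difference marks a doublet."""

    light: Stub
    heavy: Stub

    @property
    def delta_mass(self) -> float:
        return self.heavy.mass - self.light.mass

    def __post_init__(self) -> None:
        if self.delta_mass <= 0:
            raise ValueError(
                f"doublet pair ({self.light.label}, {self.heavy.label}) "
                "must have heavy.mass > light.mass"
            )


@dataclass(frozen=True)
class CrosslinkerDefinition:
    """A cleavable cross-linker: stubs, active doublet pairs, intact mass."""

    name: str
    full_mass: float  # intact linker residual mass on the cross-linked pair
    stubs: tuple[Stub, ...]
    doublet_pairs: tuple[DoubletPair, ...]  # active pairs used for matching

    def __post_init__(self) -> None:
        labels = [s.label for s in self.stubs]
        if len(set(labels)) != len(labels):
            raise ValueError("stub labels must be unique")
        known = set(labels)
        for pair in self.doublet_pairs:
            for stub in (pair.light, pair.heavy):
                if stub.label not in known:
                    raise ValueError(f"pair references unknown stub {stub.label!r}")
            # the complementary stub mass (full - light) must be physical
            if pair.light.mass >= self.full_mass:
                raise ValueError(
                    f"light stub {pair.light.label!r} mass exceeds full linker mass"
                )

    def stub(self, label: str) -> Stub:
        for s in self.stubs:
            if s.label == label:
                return s
        raise KeyError(label)


# DSSO stub elemental compositions.  The sulfenic-acid stub is the thiol plus
# water; alkene + sulfenic acid reconstitute the intact linker.
DSSO_COMPOSITIONS = {
    "A": "C3H2O",    # alkene
    "S": "C3H4O2S",  # sulfenic acid
    "T": "C3H2OS",   # thiol = sulfenic acid - H2O
}


def dsso(active_pairs: tuple[tuple[str, str], ...] = (("A", "T"),)) -> CrosslinkerDefinition:
    """DSSO with stubs A/S/T; only the (A, T) doublet pair is active by default.

    The S-containing doublets exist chemically but are disabled by default;
    pass e.g. ``active_pairs=(("A", "T"), ("A", "S"))`` to enable them.
    """
    stubs = {lab: Stub(lab, composition_mass(comp)) for lab, comp in DSSO_COMPOSITIONS.items()}
    pairs = tuple(DoubletPair(stubs[lo], stubs[hi]) for lo, hi in active_pairs)
    full = stubs["A"].mass + stubs["S"].mass  # cleavage conserves the linker
    return CrosslinkerDefinition(
        name="DSSO",
        full_mass=full,
        stubs=(stubs["A"], stubs["S"], stubs["T"]),
        doublet_pairs=pairs,
    )


def load_crosslinker(section: dict) -> CrosslinkerDefinition:
    """Build a validated :class:`CrosslinkerDefinition` from a config mapping.

    Expected keys::

        name: DSBU
        stubs:                       # each with 'label' and 'composition' or 'mass'
          - {label: B, composition: C4H5N O}
          - {label: Bs, mass: 111.032}
        doublet_pairs: [[B, Bs]]     # [light, heavy] label pairs
        full_mass: 196.085           # or full_mass_from: [B, Bs] (sum of stubs)

    Stub masses given as compositions are derived from the shared atomic-mass
    table at load time.  Invariant violations raise ``ValueError``.
    """
    try:
        name = section["name"]
        stub_specs = section["stubs"]
        pair_specs = section["doublet_pairs"]
    except KeyError as exc:
        raise ValueError(f"cross-linker config missing key {exc}") from exc

    stubs: dict[str, Stub] = {}
    for spec in stub_specs:
        label = spec["label"]
        if label in stubs:
            raise ValueError(f"duplicate stub label {label!r}")
        if "composition" in spec:
            m = composition_mass(spec["composition"])
        elif "mass" in spec:
            m = float(spec["mass"])
        else:
            raise ValueError(f"stub {label!r} needs 'composition' or 'mass'")
        stubs[label] = Stub(label, m)

    pairs = []
    for lo, hi in pair_specs:
        if lo not in stubs or hi not in stubs:
            raise ValueError(f"doublet pair ({lo}, {hi}) references unknown stub")
        pairs.append(DoubletPair(stubs[lo], stubs[hi]))

    if "full_mass" in section:
        full = float(section["full_mass"])
    elif "full_mass_from" in section:
        full = sum(stubs[lab].mass for lab in section["full_mass_from"])
    else:
        raise ValueError("cross-linker config needs 'full_mass' or 'full_mass_from'")

    return CrosslinkerDefinition(
        name=name, full_mass=full, stubs=tuple(stubs.values()), doublet_pairs=tuple(pairs)
    )
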