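"""Synthetic MS2 spectra with known ground truth.

The generator emulates centroided CID MS2 spectra of three scan classes:

* ``crosslinked`` — a cross-linked peptide pair.  Backbone b/y fragments of
  both peptides are planted, and each peptide additionally appears as the
  light/heavy stub-doublet pair (peptide+alkene, peptide+thiol for DSSO)
  produced by in-source linker cleavage, at the same charge.
* ``linear`` — an unmodified linear peptide: b/y fragments only, no doublet.
* ``linear_modified`` — a linear peptide carrying a hydrolyzed cross-linker.
  Its cleavage also produces a stub doublet, but the precursor accounts for
  a single peptide, so the second-peptide-mass filter must reject it.

Every species gets an isotope envelope (geometric intensity decay at the
averaged 1.00335/z gap), optional bounded-uniform ppm jitter, and optional
uniform noise peaks.  All draws come from one seeded generator, so a seed
fully determines the output.

Ground-truth guarantee: species are redrawn until no two cross-species
envelope/ladder positions fall within a 25 ppm guard band and no non-planted
same-charge species pair sits within 30 ppm of an active doublet spacing.
Noise peaks keep 25 ppm clearance from planted positions.  Under these
guarantees a noise-free scan's expected trigger decision is exact: planted
doublets are the only doublets the spectrum can contain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import ISOTOPE_GAP, CrosslinkerDefinition, dsso
from .fragments import PeptideIon, fragment_mzs, mz_from_neutral, peptide_neutral_mass, WATER_MASS
from .spectra import Peak, PrecursorInfo, Spectrum

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CLASSES = ("crosslinked", "linear", "linear_modified")

# guard bands of the ground-truth guarantee (see module docstring)
POSITION_GUARD_PPM = 25.0
DOUBLET_GUARD_PPM = 30.0
MAX_REDRAWS = 500


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic acquisition run."""

    n_scans: int = 100
    class_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)  # crosslinked, linear, linear_modified
    peptide_length_range: tuple[int, int] = (7, 14)
    min_peptide_mass: float = 600.0
    precursor_charge_range: tuple[int, int] = (3, 5)
    doublet_charge_range: tuple[int, int] = (1, 2)
    envelope_depth_range: tuple[int, int] = (3, 4)
    isotope_decay: float = 0.6
    n_noise_peaks: int = 0
    suppressed_partner_fraction: float = 0.0
    mass_jitter_ppm: float = 0.0  # bounded uniform, ± this many ppm per peak
    # near-miss doublet decoys per scan: same-charge species pairs planted at
    # the doublet spacing plus a random ppm offset, emulating the continuum
    # of random near-matches that dense real spectra contain.  They are
    # "spurious" by construction and drive the tolerance trade-off.
    decoy_pairs_per_scan: int = 0
    decoy_offset_ppm_range: tuple[float, float] = (0.5, 18.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class mix proportions must sum to 1")
        if self.peptide_length_range[0] < 3:
            raise ValueError("peptides must be at least 3 residues")


@dataclass
class _Species:
    """One analyte species before isotope expansion."""

    mono_mz: float
    charge: int
    base_intensity: float
    kind: str  # "backbone" | "doublet_light" | "doublet_heavy"
    peptide_index: int = 0  # 1 or 2 for doublet species


def _class_counts(n: int, mix: tuple[float, float, float]) -> list[int]:
    """Deterministic largest-remainder allocation of n scans to classes."""
    raw = [n * p for p in mix]
    counts = [int(x) for x in raw]
    order = sorted(range(len(mix)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


def _random_peptide(rng: np.random.Generator, scenario: SyntheticScenario) -> str:
    lo, hi = scenario.peptide_length_range
    while True:
        length = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
        seq = body + ("K" if rng.random() < 0.5 else "R")  # tryptic C-terminus
        if peptide_neutral_mass(seq) >= scenario.min_peptide_mass:
            return seq


def _link_site(rng: np.random.Generator, seq: str) -> tuple[str, int]:
    """Force a lysine at a random internal position; link there (1-based)."""
    pos = int(rng.integers(1, len(seq)))  # 1..len-1, C-terminus excluded
    seq = seq[: pos - 1] + "K" + seq[pos:]
    return seq, pos


def _backbone_species(
    rng: np.random.Generator, seq: str
) -> list[_Species]:
    out = []
    for _, z, mz in fragment_mzs(PeptideIon(seq), "by", max_charge=1):
        out.append(
            _Species(mono_mz=mz, charge=z, base_intensity=float(rng.uniform(1e3, 3e4)), kind="backbone")
        )
    return out


def _doublet_species(
    rng: np.random.Generator,
    scenario: SyntheticScenario,
    pep_neutral: float,
    xl: CrosslinkerDefinition,
    peptide_index: int,
    suppress_heavy: bool,
) -> list[_Species]:
    pair = xl.doublet_pairs[0]
    lo, hi = scenario.doublet_charge_range
    z = int(rng.integers(lo, hi + 1))
    out = [
        _Species(
            mono_mz=mz_from_neutral(pep_neutral + pair.light.mass, z),
            charge=z,
            base_intensity=float(rng.uniform(5e4, 1e5)),
            kind="doublet_light",
            peptide_index=peptide_index,
        )
    ]
    if not suppress_heavy:
        out.append(
            _Species(
                mono_mz=mz_from_neutral(pep_neutral + pair.heavy.mass, z),
                charge=z,
                base_intensity=float(rng.uniform(5e4, 1e5)),
                kind="doublet_heavy",
                peptide_index=peptide_index,
            )
        )
    return out


def _decoy_species(
    rng: np.random.Generator,
    scenario: SyntheticScenario,
    xl: CrosslinkerDefinition,
) -> list[tuple[_Species, _Species]]:
    """Near-miss doublet pairs: spacing = delta/z offset by a random ppm."""
    pair = xl.doublet_pairs[0]
    lo, hi = scenario.doublet_charge_range
    off_lo, off_hi = scenario.decoy_offset_ppm_range
    out = []
    for _ in range(scenario.decoy_pairs_per_scan):
        z = int(rng.integers(lo, hi + 1))
        light_mz = float(rng.uniform(300.0, 1200.0))
        offset_ppm = float(rng.uniform(off_lo, off_hi)) * (1 if rng.random() < 0.5 else -1)
        partner = light_mz + pair.delta_mass / z
        heavy_mz = partner * (1.0 + offset_ppm * 1e-6)
        out.append(
            (
                _Species(light_mz, z, float(rng.uniform(1e3, 3e4)), "decoy"),
                _Species(heavy_mz, z, float(rng.uniform(1e3, 3e4)), "decoy"),
            )
        )
    return out


def _guard_positions(sp: _Species, depth: int) -> np.ndarray:
    """Envelope member positions plus one extra ladder step."""
    z = max(sp.charge, 1)
    return sp.mono_mz + np.arange(depth + 1) * (ISOTOPE_GAP / z)


def _species_conflict(
    species: list[_Species],
    depths: list[int],
    xl: CrosslinkerDefinition,
    planted_pairs: set[tuple[int, int]],
) -> bool:
    """True if the species list violates a ground-truth guard band."""
    positions = [_guard_positions(s, d) for s, d in zip(species, depths)]
    n = len(species)
    for i in range(n):
        for j in range(i + 1, n):
            # minimum cross-species position separation
            diff = np.abs(positions[i][:, None] - positions[j][None, :])
            limit = POSITION_GUARD_PPM * 1e-6 * max(positions[i][-1], positions[j][-1])
            if diff.min() < limit:
                return True
    # no accidental doublet spacings between non-planted same-charge pairs
    for pair in xl.doublet_pairs:
        for i in range(n):
            for j in range(n):
                if i == j or species[i].charge != species[j].charge:
                    continue
                if (i, j) in planted_pairs:
                    continue
                z = species[i].charge
                theo = species[i].mono_mz + pair.delta_mass / z
                if abs(species[j].mono_mz - theo) < DOUBLET_GUARD_PPM * 1e-6 * theo:
                    return True
    return False


def _expand_peaks(
    rng: np.random.Generator,
    scenario: SyntheticScenario,
    species: list[_Species],
    depths: list[int],
) -> list[Peak]:
    peaks: list[Peak] = []
    j = scenario.mass_jitter_ppm
    for sp, depth in zip(species, depths):
        z = max(sp.charge, 1)
        for k in range(depth):
            mz = sp.mono_mz + k * ISOTOPE_GAP / z
            if j > 0:
                mz *= 1.0 + float(rng.uniform(-j, j)) * 1e-6
            peaks.append(Peak(mz, sp.base_intensity * scenario.isotope_decay**k))
    return peaks


def _add_noise(
    rng: np.random.Generator,
    scenario: SyntheticScenario,
    peaks: list[Peak],
    species: list[_Species],
    depths: list[int],
) -> list[Peak]:
    if scenario.n_noise_peaks <= 0:
        return peaks
    guard = np.concatenate([_guard_positions(s, d) for s, d in zip(species, depths)])
    lo = min(p.mz for p in peaks) * 0.9
    hi = max(p.mz for p in peaks) * 1.05
    median_int = float(np.median([s.base_intensity for s in species if s.kind == "backbone"] or [1e4]))
    out = list(peaks)
    added = 0
    while added < scenario.n_noise_peaks:
        mz = float(rng.uniform(lo, hi))
        if np.abs(guard - mz).min() < POSITION_GUARD_PPM * 1e-6 * mz:
            continue
        intensity = min(float(rng.lognormal(np.log(median_int / 4), 0.7)), median_int)
        out.append(Peak(mz, intensity))
        added += 1
    return out


def generate(
    scenario: SyntheticScenario,
    xl: CrosslinkerDefinition | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Generate spectra and the matching ground-truth table.

    Returns the spectra (scan ids ``scan=1..n``) and a DataFrame with one row
    per scan: class, peptide sequences, link sites, charges, planted doublet
    m/z values and the expected trigger decision.
    """
    xl = xl if xl is not None else dsso()
    pair = xl.doublet_pairs[0]
    rng = np.random.default_rng(scenario.seed)
    counts = _class_counts(scenario.n_scans, scenario.class_mix)
    classes: list[str] = []
    for cls, cnt in zip(CLASSES, counts):
        classes.extend([cls] * cnt)

    spectra: list[Spectrum] = []
    records: list[dict] = []
    for scan_no, cls in enumerate(classes, start=1):
        for _attempt in range(MAX_REDRAWS):
            rec: dict = {
                "scan_id": f"scan={scan_no}",
                "cls": cls,
                "peptide1": "",
                "peptide2": "",
                "link_pos1": 0,
                "link_pos2": 0,
                "precursor_charge": 0,
                "doublet_charge1": 0,
                "doublet_charge2": 0,
                "p1_light_mz": np.nan,
                "p1_heavy_mz": np.nan,
                "p2_light_mz": np.nan,
                "p2_heavy_mz": np.nan,
                "modification_mass": 0.0,
                "expected_trigger": False,
            }
            species: list[_Species] = []
            planted: set[tuple[int, int]] = set()
            z_lo, z_hi = scenario.precursor_charge_range
            z_p = int(rng.integers(z_lo, z_hi + 1))

            if cls == "crosslinked":
                pep1, pos1 = _link_site(rng, _random_peptide(rng, scenario))
                pep2, pos2 = _link_site(rng, _random_peptide(rng, scenario))
                n1, n2 = peptide_neutral_mass(pep1), peptide_neutral_mass(pep2)
                precursor_neutral = n1 + n2 + xl.full_mass
                species += _backbone_species(rng, pep1)
                species += _backbone_species(rng, pep2)
                sup1 = rng.random() < scenario.suppressed_partner_fraction
                sup2 = rng.random() < scenario.suppressed_partner_fraction
                d1 = _doublet_species(rng, scenario, n1, xl, 1, sup1)
                d2 = _doublet_species(rng, scenario, n2, xl, 2, sup2)
                base = len(species)
                species += d1 + d2
                if len(d1) == 2:
                    planted.add((base, base + 1))
                    planted.add((base + 1, base))
                if len(d2) == 2:
                    off = base + len(d1)
                    planted.add((off, off + 1))
                    planted.add((off + 1, off))
                rec.update(
                    peptide1=pep1,
                    peptide2=pep2,
                    link_pos1=pos1,
                    link_pos2=pos2,
                    doublet_charge1=d1[0].charge,
                    doublet_charge2=d2[0].charge,
                    p1_light_mz=d1[0].mono_mz,
                    p2_light_mz=d2[0].mono_mz,
                    expected_trigger=(not sup1) or (not sup2),
                )
                if len(d1) == 2:
                    rec["p1_heavy_mz"] = d1[1].mono_mz
                if len(d2) == 2:
                    rec["p2_heavy_mz"] = d2[1].mono_mz
            elif cls == "linear":
                pep = _random_peptide(rng, scenario)
                precursor_neutral = peptide_neutral_mass(pep)
                z_p = min(z_p, 3)
                species += _backbone_species(rng, pep)
                rec.update(peptide1=pep)
            else:  # linear_modified: hydrolyzed cross-linker on one residue
                pep, pos = _link_site(rng, _random_peptide(rng, scenario))
                n1 = peptide_neutral_mass(pep)
                mod_mass = xl.full_mass + WATER_MASS
                precursor_neutral = n1 + mod_mass
                species += _backbone_species(rng, pep)
                d1 = _doublet_species(rng, scenario, n1, xl, 1, suppress_heavy=False)
                base = len(species)
                species += d1
                planted.add((base, base + 1))
                planted.add((base + 1, base))
                rec.update(
                    peptide1=pep,
                    link_pos1=pos,
                    doublet_charge1=d1[0].charge,
                    p1_light_mz=d1[0].mono_mz,
                    p1_heavy_mz=d1[1].mono_mz,
                    modification_mass=mod_mass,
                    expected_trigger=False,
                )

            for light_sp, heavy_sp in _decoy_species(rng, scenario, xl):
                base = len(species)
                species += [light_sp, heavy_sp]
                # guard-exempt: a decoy pair is deliberately near the doublet
                # spacing, but it is not ground truth (never in the truth table)
                planted.add((base, base + 1))
                planted.add((base + 1, base))

            d_lo, d_hi = scenario.envelope_depth_range
            depths = [int(rng.integers(d_lo, d_hi + 1)) for _ in species]
            if not _species_conflict(species, depths, xl, planted):
                break
        else:
            raise RuntimeError(
                f"could not draw a conflict-free scan after {MAX_REDRAWS} attempts"
            )

        rec["precursor_charge"] = z_p
        peaks = _expand_peaks(rng, scenario, species, depths)
        peaks = _add_noise(rng, scenario, peaks, species, depths)
        spectra.append(
            Spectrum(
                scan_id=rec["scan_id"],
                ms_level=2,
                peaks=sorted(peaks, key=lambda p: p.mz),
                precursor=PrecursorInfo(
                    mz=mz_from_neutral(precursor_neutral, z_p), charge=z_p
                ),
            )
        )
        records.append(rec)

    return spectra, pd.DataFrame.from_records(records)


def csm_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Ground truth reshaped as a CSM/PSM table (annotation-module schema)."""
    rows = []
    for rec in truth.itertuples():
        rows.append(
            {
                "scan_id": rec.scan_id,
                "peptide1": rec.peptide1,
                "peptide2": rec.peptide2,
                "link_pos1": rec.link_pos1,
                "link_pos2": rec.link_pos2,
                "modifications": (
                    f"1:{rec.modification_mass:.6f}@{rec.link_pos1}"
                    if rec.modification_mass
                    else ""
                ),
                "precursor_charge": rec.precursor_charge,
                "class": rec.cls,
            }
        )
    return pd.DataFrame(rows)


def sweep_tolerance(
    scenario: SyntheticScenario,
    tol_values_ppm: list[float],
    xl: CrosslinkerDefinition | None = None,
) -> pd.DataFrame:
    """Planted-doublet recovery and spurious matches as a function of the
    doublet m/z tolerance, on one seeded spectrum set.

    Recovery is the fraction of planted (light, heavy) pairs found by the
    matcher; spurious matches are matches not corresponding to a planted
    pair.  Run with a jittered scenario to expose the trade-off the default
    5 ppm tolerance balances.
    """
    from .deconvolution import deconvolute
    from .doublets import match_doublets

    xl = xl if xl is not None else dsso()
    spectra, truth = generate(scenario, xl)
    # isotope spacing errors reach twice the per-peak jitter bound, so the
    # envelope tolerance must cover that with margin or clusters fragment
    cluster_tol = max(7.0, 3.0 * scenario.mass_jitter_ppm)
    deconv = [deconvolute(s, cluster_tol_ppm=cluster_tol) for s in spectra]

    rows = []
    for tol in tol_values_ppm:
        recovered = 0
        planted_total = 0
        spurious = 0
        for spec, peaks, rec in zip(spectra, deconv, truth.itertuples()):
            planted = []
            for pep in (1, 2):
                light = getattr(rec, f"p{pep}_light_mz")
                heavy = getattr(rec, f"p{pep}_heavy_mz")
                z = getattr(rec, f"doublet_charge{pep}")
                if not (np.isnan(light) or np.isnan(heavy)):
                    planted.append((light, heavy, z))
            planted_total += len(planted)
            matches = match_doublets(peaks, xl, tol)
            hit = [False] * len(planted)
            for m in matches:
                is_planted = False
                for idx, (lmz, hmz, z) in enumerate(planted):
                    if (
                        m.charge == z
                        and abs(m.light_peak.mono_mz - lmz) < lmz * 2 * scenario.mass_jitter_ppm * 1e-6 + 1e-6
                        and abs(m.heavy_peak.mono_mz - hmz) < hmz * 2 * scenario.mass_jitter_ppm * 1e-6 + 1e-6
                    ):
                        is_planted = True
                        hit[idx] = True
                if not is_planted:
                    spurious += 1
            recovered += sum(hit)
        rows.append(
            {
                "tol_ppm": tol,
                "planted": planted_total,
                "recovered": recovered,
                "recovery": recovered / planted_total if planted_total else np.nan,
                "spurious_matches": spurious,
            }
        )
    return pd.DataFrame(rows)
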