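"""Trigger sensitivity and specificity evaluation.

Three metrics mirror the standard way MS3-trigger performance is reported:

* doublet presence — for identified CSMs, whether the trigger pipeline's
  surviving doublets cover one or both peptides (sensitivity upper bound);
* correctly-triggered fraction — how many acquired MS3 scans isolated a
  peak matching an annotated peptide+stub species of the identified CSM
  (within 20 ppm by default);
* MS3-per-MS2 rate per scan class — how many MS3 targets the algorithm
  emits for cross-linked vs linear vs linker-modified linear scans, with
  percentile-bootstrap confidence intervals.  Ideally a cross-link yields
  two (one per peptide) and the other classes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import CrosslinkerDefinition, dsso
from .deconvolution import deconvolute
from .doublets import (
    MS3Decision,
    TriggerConfig,
    apply_rank_filter,
    apply_second_peptide_filter,
    match_doublets,
)
from .fragments import PeptideIon, stub_fragment_mzs
from .spectra import Spectrum

DEFAULT_TRIGGER_TOL_PPM = 20.0
DEFAULT_ANNOTATION_TOL_PPM = 15.0
BOOTSTRAP_RESAMPLES = 10_000


@dataclass(frozen=True)
class ClassRate:
    rate: float
    ci_lo: float
    ci_hi: float
    n: int


@dataclass(frozen=True)
class EvaluationReport:
    n_csms: int
    frac_one_doublet: float
    frac_both_doublets: float
    frac_correctly_triggered: float | None
    ms3_per_ms2_by_class: dict[str, ClassRate] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_csms": self.n_csms,
            "frac_one_doublet": self.frac_one_doublet,
            "frac_both_doublets": self.frac_both_doublets,
            "frac_correctly_triggered": self.frac_correctly_triggered,
            "ms3_per_ms2_by_class": {
                cls: {"rate": r.rate, "ci_0.95": [r.ci_lo, r.ci_hi], "n": r.n}
                for cls, r in self.ms3_per_ms2_by_class.items()
            },
        }


def apply_csm_prefilters(csms: pd.DataFrame, min_peptide_length: int = 5) -> pd.DataFrame:
    """Minimum-peptide-length filter (and, when protein positions are
    present as ``prot_pos1``/``prot_pos2``, removal of sequence-consecutive
    peptide pairs, which are indistinguishable from linear peptides)."""
    keep = csms["peptide1"].str.len() >= min_peptide_length
    has_p2 = csms["peptide2"].astype(str).str.len() > 0
    keep &= ~has_p2 | (csms["peptide2"].astype(str).str.len() >= min_peptide_length)
    if {"prot_pos1", "prot_pos2"} <= set(csms.columns):
        end1 = csms["prot_pos1"] + csms["peptide1"].str.len()
        end2 = csms["prot_pos2"] + csms["peptide2"].astype(str).str.len()
        consecutive = has_p2 & (
            (csms["prot_pos2"] == end1) | (csms["prot_pos1"] == end2)
        )
        keep &= ~consecutive
    return csms[keep].reset_index(drop=True)


def _csm_stub_mzs(
    row, xl: CrosslinkerDefinition, max_charge: int
) -> tuple[list[float], list[float]]:
    """Theoretical peptide+stub m/z values for each peptide of a CSM.

    The intact-linker modification, if listed, is deliberately excluded: the
    stub species replace it after cleavage.
    """
    out: list[list[float]] = [[], []]
    for idx, (seq_col, pos_col) in enumerate(
        (("peptide1", "link_pos1"), ("peptide2", "link_pos2"))
    ):
        seq = str(row[seq_col]) if pd.notna(row[seq_col]) else ""
        pos = int(row[pos_col]) if pd.notna(row[pos_col]) else 0
        if seq and pos > 0:
            mzs = stub_fragment_mzs([(PeptideIon(seq), pos)], xl, max_charge)
            out[idx] = [mz for _, _, mz in mzs]
    return out[0], out[1]


def doublet_presence(
    csms: pd.DataFrame,
    spectra: dict[str, Spectrum],
    xl: CrosslinkerDefinition | None = None,
    config: TriggerConfig | None = None,
    annotation_tol_ppm: float = DEFAULT_ANNOTATION_TOL_PPM,
) -> pd.DataFrame:
    """Per-CSM doublet flags: does the surviving doublet list cover each
    peptide?

    Runs the trigger pipeline through the second-peptide filter on each CSM's
    spectrum and checks surviving doublet members against the theoretical
    peptide+stub m/z values of each peptide (within ``annotation_tol_ppm``).
    Returns a DataFrame with scan_id, p1_doublet, p2_doublet, n_peptide_doublets.
    CSMs whose spectrum is missing are skipped.
    """
    xl = xl if xl is not None else dsso()
    config = config if config is not None else TriggerConfig()
    rows = []
    for _, row in csms.iterrows():
        spectrum = spectra.get(row["scan_id"])
        if spectrum is None:
            continue
        peaks = deconvolute(spectrum, cluster_tol_ppm=config.cluster_tol_ppm)
        matches = match_doublets(peaks, xl, config.ms2_tol_ppm)
        matches = apply_rank_filter(matches, config.rank_cutoff)
        matches = apply_second_peptide_filter(
            matches, spectrum.precursor, xl, config.second_peptide_min_mass
        )
        max_z = max((m.charge for m in matches), default=1)
        stub1, stub2 = _csm_stub_mzs(row, xl, max_z)
        found = [False, False]
        for m in matches:
            for peak in (m.light_peak, m.heavy_peak):
                for idx, stub_mzs in enumerate((stub1, stub2)):
                    if any(
                        abs(peak.mono_mz - mz) <= mz * annotation_tol_ppm * 1e-6
                        for mz in stub_mzs
                    ):
                        found[idx] = True
        rows.append(
            {
                "scan_id": row["scan_id"],
                "p1_doublet": found[0],
                "p2_doublet": found[1],
                "n_peptide_doublets": int(found[0]) + int(found[1]),
            }
        )
    return pd.DataFrame(rows)


def correctly_triggered(
    ms3_map: pd.DataFrame,
    stub_mzs_by_scan: dict[str, list[float]],
    tol_ppm: float = DEFAULT_TRIGGER_TOL_PPM,
) -> tuple[float, int, int, int]:
    """Fraction of MS3 scans whose precursor matches an annotated stub species.

    ``ms3_map`` needs columns ms3_scan_id, parent_ms2_scan_id,
    ms3_precursor_mz.  MS3 scans whose parent is not in the annotation map
    are excluded from the fraction and counted separately.

    Returns (fraction, n_correct, n_evaluated, n_orphan); the fraction is NaN
    when nothing is evaluable.
    """
    n_correct = 0
    n_eval = 0
    n_orphan = 0
    for row in ms3_map.itertuples():
        stub_mzs = stub_mzs_by_scan.get(str(row.parent_ms2_scan_id))
        if stub_mzs is None:
            n_orphan += 1
            continue
        n_eval += 1
        mz = float(row.ms3_precursor_mz)
        if any(abs(mz - theo) <= theo * tol_ppm * 1e-6 for theo in stub_mzs):
            n_correct += 1
    frac = n_correct / n_eval if n_eval else float("nan")
    return frac, n_correct, n_eval, n_orphan


def _bootstrap_ci(
    values: np.ndarray, rng: np.random.Generator, n_boot: int = BOOTSTRAP_RESAMPLES
) -> tuple[float, float]:
    """0.95 percentile-bootstrap CI for the mean."""
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    return float(np.quantile(means, 0.025)), float(np.quantile(means, 0.975))


def specificity_rates(
    decisions: list[MS3Decision],
    classes: dict[str, str],
    seed: int = 0,
    n_boot: int = BOOTSTRAP_RESAMPLES,
) -> dict[str, ClassRate]:
    """Mean MS3 targets per MS2 scan, per scan class, with bootstrap CIs.

    Scans missing from ``classes`` are grouped as "unidentified".  Classes
    with no scans are absent from the result.
    """
    rng = np.random.default_rng(seed)
    per_class: dict[str, list[int]] = {}
    for d in decisions:
        cls = classes.get(d.scan_id, "unidentified")
        per_class.setdefault(cls, []).append(len(d.targets))
    out: dict[str, ClassRate] = {}
    for cls in sorted(per_class):
        vals = np.asarray(per_class[cls], dtype=float)
        lo, hi = _bootstrap_ci(vals, rng, n_boot)
        out[cls] = ClassRate(rate=float(vals.mean()), ci_lo=lo, ci_hi=hi, n=len(vals))
    return out


def evaluate(
    spectra: dict[str, Spectrum],
    csms: pd.DataFrame,
    decisions: list[MS3Decision],
    ms3_map: pd.DataFrame | None = None,
    xl: CrosslinkerDefinition | None = None,
    config: TriggerConfig | None = None,
    seed: int = 0,
    min_peptide_length: int = 5,
) -> EvaluationReport:
    """Full evaluation: doublet presence, correctly-triggered fraction (when
    an MS3 lineage table is given) and per-class MS3-per-MS2 rates."""
    xl = xl if xl is not None else dsso()
    config = config if config is not None else TriggerConfig()
    csms = apply_csm_prefilters(csms, min_peptide_length)

    is_csm = csms["class"] == "crosslinked" if "class" in csms.columns else csms["peptide2"].astype(str).str.len() > 0
    presence = doublet_presence(csms[is_csm], spectra, xl, config)
    n_csms = len(presence)
    frac_one = float((presence["n_peptide_doublets"] >= 1).mean()) if n_csms else float("nan")
    frac_both = float((presence["n_peptide_doublets"] == 2).mean()) if n_csms else float("nan")

    frac_ct = None
    if ms3_map is not None and len(ms3_map):
        stub_map: dict[str, list[float]] = {}
        for _, row in csms[is_csm].iterrows():
            z = int(row.get("precursor_charge", 2) or 2)
            s1, s2 = _csm_stub_mzs(row, xl, max(1, z - 1))
            stub_map[row["scan_id"]] = s1 + s2
        frac_ct, *_ = correctly_triggered(ms3_map, stub_map)

    classes = dict(zip(csms["scan_id"], csms["class"])) if "class" in csms.columns else {}
    rates = specificity_rates(decisions, classes, seed=seed)
    return EvaluationReport(
        n_csms=n_csms,
        frac_one_doublet=frac_one,
        frac_both_doublets=frac_both,
        frac_correctly_triggered=frac_ct,
        ms3_per_ms2_by_class=rates,
    )
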