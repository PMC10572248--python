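"""DNA lesion frequencies and mtDNA copy number from long-amplicon qPCR.

The assay logic: polymerase-blocking lesions make a long amplicon amplify
less than an undamaged control, and under a Poisson model of lesion counts
per strand the zero class (lesion-free templates) is what amplifies, so

    lesions per normalisation length = -ln(A_damaged / A_control)
                                        * normalisation_bp / amplicon_bp

with the mitochondrial long fragment normalised per 10 kb and the nuclear
(beta-polymerase) fragment per 6.5 kb. A short mitochondrial amplicon is
too small to contain lesions at these rates, so its background-subtracted
signal is linear in mtDNA copy number; an explicit ``calibration_factor``
(copies represented by the undamaged control) converts the control-relative
signal into copies per DNA input.

Plate layout follows the standard protocol: experimental wells plus an
undamaged 100% control, a 50% control validating the quantitative range,
and no-template background wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import ValidationError
from .pileup import DataError
from .synthetic_data import DEFAULT_AMPLICON_BP

MITO_NORMALIZATION_BP = 10_000
NUCLEAR_NORMALIZATION_BP = 6_500

WELL_COLUMNS = ["well_id", "sample_id", "target", "role", "fluorescence"]
TARGETS = ("LMITO", "SMITO", "BPOL")
ROLES = ("experimental", "control_100", "control_50", "no_template")


@dataclass
class QpcrPlate:
    """qPCR plate wells plus the amplicon sizes used on it."""

    wells: pd.DataFrame
    amplicon_bp: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_AMPLICON_BP))

    def __post_init__(self) -> None:
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise DataError(f"plate wells missing columns {missing}")
        if (self.wells["fluorescence"] < 0).any():
            raise DataError("negative fluorescence reading")
        bad_roles = set(self.wells["role"]) - set(ROLES)
        if bad_roles:
            raise DataError(f"unknown well roles: {sorted(bad_roles)}")
        for target in self.wells.loc[self.wells["role"] == "experimental", "target"].unique():
            if not ((self.wells["target"] == target) & (self.wells["role"] == "control_100")).any():
                raise DataError(f"target {target} has no control_100 well")

    def select(self, target: str, role: str, sample_id: str | None = None) -> pd.Series:
        w = self.wells
        mask = (w["target"] == target) & (w["role"] == role)
        if sample_id is not None and role == "experimental":
            mask &= w["sample_id"] == sample_id
        return w.loc[mask, "fluorescence"]

    def to_csv(self, path: str | Path) -> None:
        self.wells.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path, amplicon_bp: dict[str, int] | None = None) -> "QpcrPlate":
        return cls(wells=pd.read_csv(path), amplicon_bp=dict(amplicon_bp or DEFAULT_AMPLICON_BP))


@dataclass(frozen=True)
class AmplificationResult:
    rel_amp: float
    cv_sample: float
    cv_control: float
    qc_flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class LesionEstimate:
    sample_id: str
    compartment: str  # 'mitochondrial' or 'nuclear'
    lesions_per_norm: float
    relative_amplification: float
    qc_flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CopyEstimate:
    sample_id: str
    copies_per_input: float
    calibration_factor: float
    qc_flags: tuple[str, ...] = ()


def _cv(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    m = float(np.mean(values))
    return float(np.std(values, ddof=1) / m) if m != 0 else float("nan")


def relative_amplification(
    sample_wells: Sequence[float],
    control_wells: Sequence[float],
    no_template_wells: Sequence[float],
    control50_wells: Optional[Sequence[float]] = None,
    control50_tolerance: float = 0.15,
) -> AmplificationResult:
    """Background-subtracted mean sample signal over mean control signal.

    The background is the mean no-template fluorescence. A control at or
    below background is an error (the ratio is undefined). When 50% control
    wells are supplied their background-subtracted signal is checked
    against 0.5 +/- ``control50_tolerance`` of the 100% control; an
    out-of-range value raises a QC warning and flags the result.
    """
    s = np.asarray(sample_wells, dtype=float)
    c = np.asarray(control_wells, dtype=float)
    nt = np.asarray(no_template_wells, dtype=float)
    if len(s) == 0 or len(c) == 0:
        raise DataError("need >= 1 sample and >= 1 control replicate")
    bg = float(np.mean(nt)) if len(nt) else 0.0
    c_signal = float(np.mean(c)) - bg
    if c_signal <= 0:
        raise DataError("control fluorescence at or below background")
    s_signal = float(np.mean(s)) - bg
    rel = s_signal / c_signal
    flags: list[str] = []
    if control50_wells is not None and len(control50_wells):
        half = (float(np.mean(np.asarray(control50_wells, dtype=float))) - bg) / c_signal
        if abs(half - 0.5) > control50_tolerance:
            flags.append("control50_out_of_range")
            warnings.warn(
                f"50% control at {half:.3f} of the undamaged control "
                f"(expected 0.5 +/- {control50_tolerance}); quantitative range suspect",
                stacklevel=2,
            )
    return AmplificationResult(
        rel_amp=rel, cv_sample=_cv(s), cv_control=_cv(c), qc_flags=tuple(flags)
    )


def lesion_frequency(
    rel_amp: float,
    amplicon_bp: int,
    normalization_bp: int,
    clip_tolerance: float = 0.05,
) -> float:
    """Lesions per ``normalization_bp`` from a relative amplification.

    ``-ln(rel_amp) * normalization_bp / amplicon_bp``; exactly 0 at
    rel_amp 1. Values slightly above 1 (undamaged-sample variability, up to
    ``1 + clip_tolerance``) are clipped to 1 with a warning; rel_amp <= 0
    or beyond the tolerance is an error.
    """
    if amplicon_bp <= 0 or normalization_bp <= 0:
        raise ValidationError("amplicon_bp and normalization_bp must be > 0")
    if rel_amp <= 0:
        raise DataError("relative amplification must be > 0")
    if rel_amp > 1 + clip_tolerance:
        raise DataError(
            f"relative amplification {rel_amp:.4f} exceeds 1 + {clip_tolerance}"
        )
    if rel_amp > 1:
        warnings.warn(
            f"relative amplification {rel_amp:.4f} > 1 clipped to 1 (no damage)",
            stacklevel=2,
        )
        rel_amp = 1.0
    return -np.log(rel_amp) * normalization_bp / amplicon_bp


def copy_number(
    smito_wells: Sequence[float],
    control_wells: Sequence[float],
    calibration_factor: float,
    no_template_wells: Sequence[float] = (),
) -> CopyEstimate:
    """mtDNA copies per DNA input from the short mito amplicon.

    copies = calibration_factor * (background-subtracted SMITO signal,
    normalised to the undamaged control). Linear and deterministic; a
    non-positive background-subtracted signal yields 0 copies with a QC
    warning.
    """
    if calibration_factor <= 0:
        raise ValidationError("calibration_factor must be > 0")
    if len(smito_wells) == 0:
        raise DataError("missing SMITO wells")
    res = relative_amplification(smito_wells, control_wells, no_template_wells)
    copies = calibration_factor * res.rel_amp
    flags = list(res.qc_flags)
    if copies <= 0:
        warnings.warn("non-positive SMITO signal; copy number set to 0", stacklevel=2)
        copies = 0.0
        flags.append("nonpositive_signal")
    return CopyEstimate(
        sample_id="", copies_per_input=copies,
        calibration_factor=calibration_factor, qc_flags=tuple(flags),
    )


_TARGET_SPEC = {
    "LMITO": ("mitochondrial", MITO_NORMALIZATION_BP),
    "BPOL": ("nuclear", NUCLEAR_NORMALIZATION_BP),
}


def analyze_plate(
    plate: QpcrPlate,
    calibration_factor: float,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Per-sample lesion and copy-number estimates from one plate.

    Returns a tidy table: sample_id, compartment ('mitochondrial',
    'nuclear', 'copy_number'), rel_amp, lesions_per_norm, copies_per_input,
    qc_flags.
    """
    samples = (
        [sample_id]
        if sample_id is not None
        else sorted(plate.wells.loc[plate.wells["role"] == "experimental", "sample_id"].unique())
    )
    rows = []
    for sid in samples:
        for target, (compartment, norm_bp) in _TARGET_SPEC.items():
            if target not in set(plate.wells["target"]):
                continue
            res = relative_amplification(
                plate.select(target, "experimental", sid),
                plate.select(target, "control_100"),
                plate.select(target, "no_template"),
                control50_wells=plate.select(target, "control_50"),
            )
            flags = list(res.qc_flags)
            if 0 < res.rel_amp <= 1.05:
                lesions = lesion_frequency(res.rel_amp, plate.amplicon_bp[target], norm_bp)
            else:
                lesions = float("nan")
                flags.append("rel_amp_out_of_range")
            rows.append(
                {
                    "sample_id": sid, "compartment": compartment,
                    "rel_amp": res.rel_amp, "lesions_per_norm": lesions,
                    "copies_per_input": float("nan"),
                    "qc_flags": ";".join(flags),
                }
            )
        est = copy_number(
            plate.select("SMITO", "experimental", sid),
            plate.select("SMITO", "control_100"),
            calibration_factor,
            plate.select("SMITO", "no_template"),
        )
        rows.append(
            {
                "sample_id": sid, "compartment": "copy_number",
                "rel_amp": est.copies_per_input / calibration_factor,
                "lesions_per_norm": float("nan"),
                "copies_per_input": est.copies_per_input,
                "qc_flags": ";".join(est.qc_flags),
            }
        )
    return pd.DataFrame(rows)
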