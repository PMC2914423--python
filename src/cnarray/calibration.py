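"""Intensity <-> copy-number response model.

Normalized array signals are calibrated so that a diploid locus yields a
signal of 2.0, but the array response is not linear in copy number: at low
copy number the signal is compressed (CN=1 reads 1.14, not 1.0) and at high
copy number it saturates into a shallow linear regime.  This module encodes
the calibrated response ``S0(c)``, the contamination/ploidy-adjusted
expected signal

    S(c) = beta * (2*alpha + (1 - alpha) * S0(c)),

where ``alpha`` is the fraction of benign diploid DNA in the sample and
``beta`` rescales for the average copy number of the aneuploid genome
differing from 2, and the delta-delta-Ct utility used to anchor the
high-CN end of the calibration with qPCR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "SignalCalibration",
    "SampleModel",
    "MODES",
    "MAX_CN",
    "DEFAULT_S0_TABLE",
    "expected_signal_s0",
    "expected_signal",
    "qpcr_copy_number",
]

#: Largest copy-number state considered anywhere in the package.
MAX_CN = 70

#: Calibrated median signal at integer copy numbers 0..5.  CN=2 is the
#: normalization anchor; the other values come from samples of known
#: karyotype (homozygous deletion, male X, 47,XXX, 48,XXXX, 49,XXXXX).
DEFAULT_S0_TABLE: Mapping[int, float] = {
    0: 0.36,
    1: 1.14,
    2: 2.0,
    3: 2.72,
    4: 3.41,
    5: 4.1,
}

DEFAULT_SLOPE = 0.314
DEFAULT_INTERCEPT = 3.41

MODES = ("normal", "cell_line", "tumor", "agilent")


def _interp_knots(table: Mapping[int, float], slope: float, intercept: float) -> tuple[float, float]:
    """Knots for CN 6 and 7, linearly interpolated between the tabulated
    S0(5) and the linear-regime value at CN 8.  Keeps S0 strictly
    increasing and nearly continuous across the table/line boundary."""
    lo = table[5]
    hi = slope * 8 + intercept
    step = (hi - lo) / 3.0
    return (lo + step, lo + 2 * step)


@dataclass(frozen=True)
class SignalCalibration:
    """Response curve S0(c): tabulated for c <= 5, interpolated knots for
    c in {6, 7}, linear ``slope*c + intercept`` for c >= 8."""

    table: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_S0_TABLE))
    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    interp_knots: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.interp_knots is None:
            object.__setattr__(
                self, "interp_knots", _interp_knots(self.table, self.slope, self.intercept)
            )
        v = self.s0_vector()
        if np.any(np.diff(v) <= 0):
            raise ValueError("S0(c) must be strictly increasing over 0..%d" % MAX_CN)
        if self.table[2] != 2.0:
            raise ValueError("S0(2) must equal 2.0 (normalization anchor)")

    def s0_vector(self, max_cn: int = MAX_CN) -> np.ndarray:
        """S0 evaluated at every integer CN 0..max_cn."""
        c = np.arange(max_cn + 1)
        out = self.slope * c + self.intercept
        for k in range(min(5, max_cn) + 1):
            out[k] = self.table[k]
        if max_cn >= 6:
            out[6] = self.interp_knots[0]
        if max_cn >= 7:
            out[7] = self.interp_knots[1]
        return out

    def s0(self, c: int) -> float:
        if not 0 <= c <= MAX_CN:
            raise ValueError(f"copy number {c} outside [0, {MAX_CN}]")
        if c <= 5:
            return float(self.table[c])
        if c == 6:
            return float(self.interp_knots[0])
        if c == 7:
            return float(self.interp_knots[1])
        return float(self.slope * c + self.intercept)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "table": {str(k): v for k, v in self.table.items()},
            "slope": self.slope,
            "intercept": self.intercept,
            "interp_knots": list(self.interp_knots),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SignalCalibration":
        knots = d.get("interp_knots")
        return cls(
            table={int(k): float(v) for k, v in d["table"].items()},
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            interp_knots=tuple(knots) if knots is not None else None,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SignalCalibration":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SampleModel:
    """Per-sample parameters: contamination ``alpha``, genome-size factor
    ``beta``, residual log-signal variance ``sigma2`` and the analysis mode.

    ``normal`` fixes alpha=0, beta=1 (noncancerous sample); ``cell_line``
    fixes alpha=0 (no benign contamination); ``tumor`` leaves both free;
    ``agilent`` behaves like ``tumor`` but disables the genotype-based
    peak-anchoring rules downstream.
    """

    alpha: float = 0.0
    beta: float = 1.0
    sigma2: float = 0.04
    mode: str = "normal"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if not 0.5 <= self.beta <= 2.0:
            raise ValueError("beta must be in [0.5, 2]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.mode == "normal" and (self.alpha != 0.0 or self.beta != 1.0):
            raise ValueError("normal mode requires alpha=0, beta=1")
        if self.mode == "cell_line" and self.alpha != 0.0:
            raise ValueError("cell_line mode requires alpha=0")

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "sigma2": self.sigma2, "mode": self.mode}


def expected_signal_s0(c: int, cal: SignalCalibration | None = None) -> float:
    """Calibrated expected signal for a pure, ploidy-2 sample at CN ``c``."""
    cal = cal or SignalCalibration()
    return cal.s0(c)


def expected_signal(c, model: SampleModel, cal: SignalCalibration | None = None):
    """Expected signal S(c) = beta*(2*alpha + (1-alpha)*S0(c)).

    ``c`` may be an int or an integer array; the return matches.
    """
    cal = cal or SignalCalibration()
    c_arr = np.asarray(c)
    s0v = cal.s0_vector()[c_arr]
    out = model.beta * (2.0 * model.alpha + (1.0 - model.alpha) * s0v)
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def qpcr_copy_number(
    ct_gene_cellline: float,
    ct_ref_cellline: float,
    ct_gene_refsample: float,
    ct_ref_refsample: float,
) -> float:
    """Delta-delta-Ct copy number: 2**(1 - CTgc + CTrc + CTgr - CTrr).

    The reference gene is assumed to have two copies in both samples, hence
    the +1 in the exponent (equal Ct values give CN=2).
    """
    exponent = 1.0 - ct_gene_cellline + ct_ref_cellline + ct_gene_refsample - ct_ref_refsample
    return float(2.0 ** exponent)
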