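"""End-to-end analysis reports in the classic meta-analysis table layout.

:func:`analyze` runs the full estimator battery on a dataset and arranges
the results as one row per method: the fixed-effect fit; each
random-effects τ² estimator with its companion interval (DL with
Q-profile, J with the generalized-Q interval, REML with profile
likelihood, MP) and its inverse-variance-weighted λ and Wald interval;
the Biggerstaff–Jackson τ² interval (interval only); the HKSJ intervals
with DL and MP plug-ins; and the sample-size-weighted estimate with its
t-based companion interval.  With ``bias_correct`` the same rows are
repeated for the bias-corrected study effects; with ``exp_scale`` the
ratio-of-means columns exp(λ̂) and exponentiated bounds are appended
(a formatting transform, not a separate estimator).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import MetaDataset, read_dataset
from .effects import precision_flag
from .pooling import hksj_interval, iv_weighted_mean, ssw_interval, ssw_mean, wald_interval
from .tau2 import estimate_tau2
from .tau2_ci import tau2_interval

__all__ = ["AnalysisReport", "analyze", "analyze_file", "REPORT_COLUMNS"]

logger = logging.getLogger("lrrmeta")

REPORT_COLUMNS = [
    "model",
    "method",
    "tau2",
    "tau2_lo",
    "tau2_hi",
    "lambda",
    "lambda_lo",
    "lambda_hi",
    "ci_length",
]
EXP_COLUMNS = ["rom", "rom_lo", "rom_hi"]


@dataclass
class AnalysisReport:
    """A per-method results table plus provenance."""

    label: str
    table: pd.DataFrame
    level: float = 0.95
    bias_corrected: bool = False
    source: str | None = None
    version: str = field(default_factory=lambda: __version__)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")

    def to_text(self, decimals: int = 4) -> str:
        """Aligned text rendering with a fixed number of decimals."""
        out = self.table.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].map(
                    lambda v: "" if pd.isna(v) else f"{v:.{decimals}f}"
                )
        header = (
            f"dataset: {self.label}   level: {self.level:g}   "
            f"bias-corrected: {self.bias_corrected}   lrrmeta {self.version}"
        )
        return header + "\n" + out.to_string(index=False)


def _battery(data: MetaDataset, level: float) -> list[dict]:
    """One pass of every method over one dataset -> list of row dicts."""
    tau2s = {m: estimate_tau2(data, m) for m in ("DL", "J", "MP", "REML")}
    for m, fit in tau2s.items():
        logger.info(
            "tau2 %s: %.6g (converged=%s truncated=%s)",
            m, fit.tau2, fit.converged, fit.truncated,
        )
    cis = {m: tau2_interval(data, m, level) for m in ("QP", "BJ", "J", "PL")}

    def row(model, method, tau2=None, tci=None, lam=None):
        r = dict.fromkeys(REPORT_COLUMNS, np.nan)
        r["model"], r["method"] = model, method
        if tau2 is not None:
            r["tau2"] = tau2
        if tci is not None:
            r["tau2_lo"], r["tau2_hi"] = tci.lower, tci.upper
        if lam is not None:
            r["lambda"], r["lambda_lo"], r["lambda_hi"] = lam.estimate, lam.lower, lam.upper
            r["ci_length"] = lam.upper - lam.lower
        return r

    fe = wald_interval(iv_weighted_mean(data, 0.0), level)
    re_wald = {
        m: wald_interval(iv_weighted_mean(data, tau2s[m].tau2, tau2_method=m), level)
        for m in ("DL", "J", "MP", "REML")
    }
    return [
        row("FE", "IV", tau2=0.0, lam=fe),
        row("RE", "DL, QP", tau2=tau2s["DL"].tau2, tci=cis["QP"], lam=re_wald["DL"]),
        row("RE", "BJ", tci=cis["BJ"]),
        row("RE", "J", tau2=tau2s["J"].tau2, tci=cis["J"], lam=re_wald["J"]),
        row("RE", "REML, PL", tau2=tau2s["REML"].tau2, tci=cis["PL"], lam=re_wald["REML"]),
        row("RE", "MP", tau2=tau2s["MP"].tau2, lam=re_wald["MP"]),
        row("RE", "HKSJ (DL)", lam=hksj_interval(data, tau2s["DL"].tau2, level, "DL")),
        row("RE", "HKSJ MP", lam=hksj_interval(data, tau2s["MP"].tau2, level, "MP")),
        row(
            "RE",
            "SSW, SSW MP",
            lam=ssw_interval(data, level, tau2=tau2s["MP"].tau2),
        ),
    ]


def analyze(
    data: MetaDataset,
    level: float = 0.95,
    bias_correct: bool = False,
    exp_scale: bool = False,
    label: str = "dataset",
    source: str | None = None,
) -> AnalysisReport:
    """Run all point/interval methods on a dataset.

    With ``bias_correct`` (requires arm-level summaries) every row is
    repeated for the bias-corrected study effects, labelled with a
    leading Δ.  Warns per study failing the √n·mean/sd ≥ 3 precision
    rule; the rule never filters studies.
    """
    if data.arms is not None:
        for sid, (t, c) in zip(data.labels, data.arms):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # zero-SD warning handled here
                ok = precision_flag(t) or precision_flag(c)
            if not ok:
                warnings.warn(
                    f"study {sid!r}: both arms have sqrt(n)*mean/sd < 3; "
                    "the normal approximation to its LRR may be poor"
                )

    rows = _battery(data, level)
    if bias_correct:
        corrected = data.with_bias_correction(True)
        for r in _battery(corrected, level):
            r["method"] = f"Δ & {r['method']}"
            rows.append(r)

    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if exp_scale:
        table["rom"] = np.exp(table["lambda"])
        table["rom_lo"] = np.exp(table["lambda_lo"])
        table["rom_hi"] = np.exp(table["lambda_hi"])
    return AnalysisReport(
        label=label,
        table=table,
        level=level,
        bias_corrected=bias_correct,
        source=source,
    )


def analyze_file(path: str | Path, **kwargs) -> AnalysisReport:
    """Read a study-summary CSV and analyze it."""
    path = Path(path)
    data = read_dataset(path)
    kwargs.setdefault("label", path.stem)
    return analyze(data, source=str(path), **kwargs)
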