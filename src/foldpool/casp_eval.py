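"""The CASP-style two-pass trimmed Z-score protocol.

Per evaluation unit (domain), every predictor's top-1 GDT-TS is standardized
against the field; scores whose first-pass Z falls below -2 are treated as
outliers and the statistics are recomputed once over the survivors. A
predictor's headline number is the sum over domains of max(Z, 0), and
alternative conformations of the same region (v1/v2 pairs) are averaged into
one pseudo-domain before summing so they do not count twice.

Standard deviations are population (1/n) standard deviations, the assessors'
convention; with n predictors the largest attainable |Z| is sqrt(n-1), so no
exclusion can ever fire for n <= 5.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ScorePanel", "ZScoreReport", "zscores", "accumulate", "average_pairs"]

Z_CUTOFF = -2.0


@dataclass
class ScorePanel:
    """Domain x predictor GDT-TS scores (internally domains are rows)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.astype(float)
        bad = self.df.notna().sum(axis=1) < 2
        if bad.any() and bad.all():
            raise ValueError("no domain has >= 2 non-missing predictor scores")
        vals = self.df.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("GDT-TS scores must lie in [0, 1]")

    @property
    def domains(self) -> list[str]:
        return list(self.df.index)

    @property
    def predictors(self) -> list[str]:
        return list(self.df.columns)

    def write(self, path: str | Path) -> None:
        # external convention: rows = predictors, columns = domains
        out = self.df.T.copy()
        out.index.name = "predictor"
        out.to_csv(path)

    @classmethod
    def read(cls, path: str | Path) -> "ScorePanel":
        df = pd.read_csv(path, index_col=0)
        return cls(df=df.T)


@dataclass
class ZScoreReport:
    """Two-pass Z-scores plus exclusion flags and positive-only sums."""

    z_pass1: pd.DataFrame
    z_final: pd.DataFrame
    excluded: pd.DataFrame
    cumulative: pd.Series
    pair_map: list[tuple[str, str]] = field(default_factory=list)
    skipped_domains: list[str] = field(default_factory=list)

    @property
    def domains(self) -> list[str]:
        return list(self.z_final.index)

    @property
    def predictors(self) -> list[str]:
        return list(self.z_final.columns)

    def write_csv(self, path: str | Path) -> None:
        out = self.z_final.T.copy()
        out.index.name = "predictor"
        out["cumulative"] = self.cumulative
        out.to_csv(path, float_format="%.6f")

    def summary_json(self, path: str | Path) -> None:
        obj = {
            "cumulative": {p: float(v) for p, v in self.cumulative.items()},
            "excluded": {
                d: [p for p in self.predictors if bool(self.excluded.loc[d, p])]
                for d in self.domains
                if self.excluded.loc[d].any()
            },
            "pairs_averaged": [list(p) for p in self.pair_map],
            "skipped_domains": self.skipped_domains,
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def _domain_z(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-pass trimmed Z for one domain's score vector (NaN = missing)."""
    z1 = np.full_like(x, np.nan)
    zf = np.full_like(x, np.nan)
    excl = np.zeros(x.shape, dtype=bool)
    ok = np.isfinite(x)
    vals = x[ok]
    sd = vals.std()  # population sd
    if sd <= 1e-12:
        warnings.warn("zero score spread in a domain; all Z set to 0")
        z1[ok] = 0.0
        zf[ok] = 0.0
        return z1, zf, excl
    z1[ok] = (vals - vals.mean()) / sd
    excl[ok] = z1[ok] < Z_CUTOFF
    keep = ok & ~excl
    kept = x[keep]
    sd2 = kept.std()
    if sd2 <= 1e-12:
        warnings.warn("zero spread after trimming; all Z set to 0")
        zf[ok] = 0.0
        return z1, zf, excl
    # excluded predictors are re-scored against the trimmed statistics too
    zf[ok] = (x[ok] - kept.mean()) / sd2
    return z1, zf, excl


def zscores(panel: ScorePanel) -> ZScoreReport:
    """Run the two-pass protocol over every domain of the panel."""
    z1 = pd.DataFrame(np.nan, index=panel.domains, columns=panel.predictors)
    zf = pd.DataFrame(np.nan, index=panel.domains, columns=panel.predictors)
    excl = pd.DataFrame(False, index=panel.domains, columns=panel.predictors)
    skipped: list[str] = []
    for d in panel.domains:
        x = panel.df.loc[d].to_numpy(dtype=float)
        if np.isfinite(x).sum() < 2:
            warnings.warn(f"domain {d!r} has < 2 usable scores; skipped")
            skipped.append(d)
            continue
        a, b, e = _domain_z(x)
        z1.loc[d] = a
        zf.loc[d] = b
        excl.loc[d] = e
        if e.any():
            logger.info("domain %s: excluded %s", d,
                        [p for p, f in zip(panel.predictors, e) if f])
    keep = [d for d in panel.domains if d not in skipped]
    z1, zf, excl = z1.loc[keep], zf.loc[keep], excl.loc[keep]
    report = ZScoreReport(
        z_pass1=z1, z_final=zf, excluded=excl,
        cumulative=pd.Series(dtype=float), skipped_domains=skipped,
    )
    report.cumulative = accumulate(report)
    return report


def accumulate(report: ZScoreReport) -> pd.Series:
    """Positive-only cumulative Z per predictor; missing domains add 0."""
    pos = report.z_final.clip(lower=0.0)
    return pos.sum(axis=0, skipna=True).rename("cumulative")


def average_pairs(report: ZScoreReport, pairs: list[tuple[str, str]]) -> ZScoreReport:
    """Collapse alternative-conformation domain pairs into pseudo-domains.

    Each pair (a, b) is replaced by one row named "a+b" whose Z is the mean of
    the two; the cumulative sum is recomputed over the reduced domain set.
    """
    seen: set[str] = set()
    for a, b in pairs:
        for d in (a, b):
            if d not in report.z_final.index:
                raise ValueError(f"pair domain {d!r} not in report")
            if d in seen:
                raise ValueError(f"domain {d!r} appears in more than one pair")
            seen.add(d)
    if not pairs:
        return report

    def reduce(df: pd.DataFrame, how: str) -> pd.DataFrame:
        rows: dict[str, pd.Series] = {}
        order: list[str] = []
        paired = {d for p in pairs for d in p}
        for d in df.index:
            if d not in paired:
                rows[d] = df.loc[d]
                order.append(d)
        for a, b in pairs:
            name = f"{a}+{b}"
            if how == "mean":
                rows[name] = pd.concat([df.loc[a], df.loc[b]], axis=1).mean(axis=1)
            else:
                rows[name] = df.loc[a].fillna(False) | df.loc[b].fillna(False)
            order.append(name)
        return pd.DataFrame({n: rows[n] for n in order}).T

    new = ZScoreReport(
        z_pass1=reduce(report.z_pass1, "mean"),
        z_final=reduce(report.z_final, "mean"),
        excluded=reduce(report.excluded, "or").astype(bool),
        cumulative=pd.Series(dtype=float),
        pair_map=list(pairs),
        skipped_domains=list(report.skipped_domains),
    )
    new.cumulative = accumulate(new)
    return new
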