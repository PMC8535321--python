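"""Weighted genetic risk score over risk and protective loci.

The score of a subject is the weighted sum of risk-allele counts across a
panel of susceptibility loci, the weight being the natural log of the
published odds ratio.  Protective loci use the reciprocal rule: any
allele different from the protective one counts as a risk allele, and the
weight is ln(1/OR) of the protective allele.  Dosages passed in are
therefore always counts of the scored (risk-direction) allele, 0-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RiskLocus",
    "ScorePanel",
    "locus_weight",
    "compute_wgrs",
    "compare_groups",
]


@dataclass(frozen=True)
class RiskLocus:
    """One panel entry: a SNP id or an HLA allele label with its odds ratio."""

    key: str
    odds_ratio: float
    protective: bool = False
    freq: float | None = None

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.key}: odds ratio must be positive")
        if self.freq is not None and not 0.0 <= self.freq <= 1.0:
            raise ValueError(f"{self.key}: panel frequency outside [0, 1]")


def locus_weight(locus: RiskLocus) -> float:
    """ln(OR) for risk loci; ln(1/OR) per non-protective allele otherwise."""
    return math.log(1.0 / locus.odds_ratio if locus.protective else locus.odds_ratio)


class ScorePanel:
    """An ordered panel of risk loci with unique keys."""

    def __init__(self, loci: Iterable[RiskLocus]):
        self.loci = list(loci)
        keys = [l.key for l in self.loci]
        if len(keys) != len(set(keys)):
            raise ValueError("panel locus keys must be unique")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScorePanel":
        df = pd.read_csv(path, sep="\t")
        loci = []
        for r in df.itertuples():
            freq = getattr(r, "FREQ", None)
            if freq is not None and pd.isna(freq):
                freq = None
            loci.append(
                RiskLocus(
                    key=str(r.LOCUS),
                    odds_ratio=float(r.OR),
                    protective=bool(r.PROTECTIVE),
                    freq=None if freq is None else float(freq),
                )
            )
        return cls(loci)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                (l.key, l.odds_ratio, int(l.protective), l.freq)
                for l in self.loci
            ],
            columns=["LOCUS", "OR", "PROTECTIVE", "FREQ"],
        ).to_csv(path, sep="\t", index=False, na_rep="")


def compute_wgrs(
    panel: ScorePanel,
    dosages: Mapping[str, float | None],
    missing: str = "skip",
) -> float:
    """Weighted genetic risk score for one subject.

    ``dosages`` maps locus key to the scored-allele count (0, 1 or 2; for
    protective loci this is the count of non-protective alleles).  Missing
    dosages are skipped by default; with ``missing='impute'`` a locus with
    a configured panel frequency contributes weight * 2 * freq instead.
    """
    if missing not in ("skip", "impute"):
        raise ValueError(f"unknown missing-dosage mode {missing!r}")
    score = 0.0
    for locus in panel:
        d = dosages.get(locus.key)
        if d is None or (isinstance(d, float) and math.isnan(d)):
            if missing == "impute" and locus.freq is not None:
                score += locus_weight(locus) * 2.0 * locus.freq
            continue
        if d not in (0, 1, 2):
            raise ValueError(f"{locus.key}: dosage {d} not in {{0,1,2}}")
        score += locus_weight(locus) * float(d)
    return score


def compare_groups(
    scores_a: Sequence[float], scores_b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sample t test on risk-score distributions.

    Classical equal-variance form by default (Welch behind the flag).
    Degenerate cases: fewer than two values per group is an error; zero
    pooled variance yields p = 1 when the means are equal, p = 0 (infinite
    t) when they differ.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two scores")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (math.inf if a.mean() > b.mean() else -math.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
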