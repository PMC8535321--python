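"""Variant-key normalization, genotype tables, genetic maps and summary stats.

All coordinates are 1-based GRCh37.  Genotypes are alternate-allele dosages
in {0, 1, 2}; a missing call is NaN, never 0 (0 is a valid homozygous
reference call).  The on-disk dialects are plain TSV:

* genotype table: header ``CHROM POS REF ALT AF CM`` then one column per
  individual id; missing calls written as ``.``;
* genetic map: ``CHROM POS CM`` with anchors strictly increasing in both
  coordinates within a chromosome;
* summary statistics: ``CHROM POS REF ALT P COHORT``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantKey",
    "normalize_variant_key",
    "chrom_sort_key",
    "GenotypeTable",
    "GeneticMap",
    "SummaryStatsTable",
    "merge_genotype_sets",
    "assign_allele_frequency",
    "haldane_theta",
    "vcf_to_genotype_table",
    "FREQUENCY_SOURCE_ORDER",
]

#: Priority order of population frequency sources used when assigning a
#: single analysis frequency to a variant.
FREQUENCY_SOURCE_ORDER = ("gnomad_nfe", "exac_nfe", "kg_eur")


class VariantKey(NamedTuple):
    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def normalize_variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Canonical biallelic key: trim shared allele suffix, then shared prefix.

    Trimming the shared suffix first, then the shared prefix (advancing the
    position), makes keys from different callers joinable.  At least one base
    is always kept in each allele.
    """
    chrom = str(chrom).removeprefix("chr")
    ref, alt = ref.upper(), alt.upper()
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValueError(f"ref equals alt after normalization at {chrom}:{pos}")
    return VariantKey(chrom, int(pos), ref, alt)


_CHROM_RANK = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = str(chrom).removeprefix("chr")
    return (_CHROM_RANK.get(c, 99), c)


def haldane_theta(d_cm: float) -> float:
    """Haldane map function: recombination fraction for a distance in cM.

    theta = (1 - exp(-2 d / 100)) / 2, strictly increasing on [0, inf)
    with asymptote 1/2.
    """
    if d_cm < 0:
        raise ValueError(f"map distance must be >= 0, got {d_cm}")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


class GeneticMap:
    """Per-chromosome piecewise-linear physical-to-genetic map.

    Anchors must be strictly increasing in both physical position and cM.
    Interpolation is linear between anchors and constant beyond the terminal
    anchors (no extrapolation of the local recombination rate).
    """

    def __init__(self, anchors: Mapping[str, tuple[Sequence[int], Sequence[float]]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, cm) in anchors.items():
            pos = np.asarray(pos, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            if pos.size == 0:
                raise ValueError(f"chromosome {chrom}: empty anchor list")
            if pos.size != cm.size:
                raise ValueError(f"chromosome {chrom}: anchor length mismatch")
            if np.any(np.diff(pos) <= 0) or np.any(np.diff(cm) <= 0):
                raise ValueError(
                    f"chromosome {chrom}: anchors must be strictly increasing"
                )
            self._anchors[str(chrom)] = (pos, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
        anchors = {
            str(chrom): (g["POS"].to_numpy(), g["CM"].to_numpy())
            for chrom, g in df.groupby("CHROM", sort=False)
        }
        return cls(anchors)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for chrom, (pos, cm) in self._anchors.items():
            for p, c in zip(pos, cm):
                rows.append((chrom, int(p), float(c)))
        pd.DataFrame(rows, columns=["CHROM", "POS", "CM"]).to_csv(
            path, sep="\t", index=False
        )

    def interpolate(self, chrom: str, pos: int | np.ndarray) -> float | np.ndarray:
        """cM position of ``pos`` on ``chrom`` (vectorized over positions)."""
        chrom = str(chrom).removeprefix("chr")
        if chrom not in self._anchors:
            raise KeyError(f"chromosome {chrom} not in genetic map")
        xp, fp = self._anchors[chrom]
        out = np.interp(np.asarray(pos, dtype=float), xp.astype(float), fp)
        return float(out) if np.isscalar(pos) or np.ndim(pos) == 0 else out


def interpolate_cM(gmap: GeneticMap, chrom: str, pos: int) -> float:
    """Functional alias for :meth:`GeneticMap.interpolate`."""
    return gmap.interpolate(chrom, pos)


_VARIANT_COLS = ["CHROM", "POS", "REF", "ALT", "AF", "CM"]


class GenotypeTable:
    """Biallelic variant-by-individual dosage table with map annotations.

    ``variants`` carries one row per variant (CHROM, POS, REF, ALT, AF, CM);
    ``calls`` is positionally aligned with it, one float column per
    individual, values in {0, 1, 2, NaN}.
    """

    def __init__(self, variants: pd.DataFrame, calls: pd.DataFrame):
        variants = variants.reset_index(drop=True)
        calls = calls.reset_index(drop=True)
        missing = [c for c in _VARIANT_COLS if c not in variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        if len(variants) != len(calls):
            raise ValueError("variants and calls have different lengths")
        bad = ~(calls.isna() | calls.isin([0, 1, 2]))
        if bad.to_numpy().any():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self.variants = variants
        self.calls = calls.astype(float)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.columns)

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(str(r.CHROM), int(r.POS), str(r.REF), str(r.ALT))
            for r in self.variants.itertuples()
        ]

    def sort_genomic(self) -> "GenotypeTable":
        order = sorted(
            range(self.n_variants),
            key=lambda i: (
                chrom_sort_key(self.variants.CHROM.iat[i]),
                int(self.variants.POS.iat[i]),
            ),
        )
        return GenotypeTable(
            self.variants.iloc[order], self.calls.iloc[order]
        )

    def with_cm_from(self, gmap: GeneticMap) -> "GenotypeTable":
        cm = [
            gmap.interpolate(str(r.CHROM), int(r.POS))
            for r in self.variants.itertuples()
        ]
        variants = self.variants.copy()
        variants["CM"] = cm
        return GenotypeTable(variants, self.calls)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"CHROM": str}, na_values=["."])
        variants = df[_VARIANT_COLS]
        calls = df.drop(columns=_VARIANT_COLS)
        return cls(variants, calls)

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat([self.variants, self.calls], axis=1)
        out.to_csv(path, sep="\t", index=False, na_rep=".")

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeTable({self.n_variants} variants x {len(self.individuals)} individuals)"


def merge_genotype_sets(
    a: GenotypeTable, b: GenotypeTable, freq_conflict_tol: float = 0.2
) -> GenotypeTable:
    """Union of two genotype tables; the first argument wins on shared keys.

    Individuals present in only one source get missing calls for the other
    source's variants.  Shared keys whose allele frequencies disagree by more
    than ``freq_conflict_tol`` (likely strand or allele mismatches) raise a
    warning; the priority source's record is kept either way.
    """
    keys_a = a.keys()
    seen = set(keys_a)
    keep_b = [i for i, k in enumerate(b.keys()) if k not in seen]
    dup_b = [i for i, k in enumerate(b.keys()) if k in seen]
    if dup_b:
        af_a = dict(zip(keys_a, a.variants.AF))
        bk = b.keys()
        for i in dup_b:
            fa, fb = af_a[bk[i]], b.variants.AF.iat[i]
            if pd.notna(fa) and pd.notna(fb) and abs(fa - fb) > freq_conflict_tol:
                warnings.warn(
                    f"allele-frequency conflict at {bk[i]}: {fa:.3f} vs {fb:.3f}; "
                    "keeping priority source",
                    stacklevel=2,
                )
    variants = pd.concat(
        [a.variants, b.variants.iloc[keep_b]], ignore_index=True
    )
    all_ind = list(dict.fromkeys(a.individuals + b.individuals))
    calls_a = a.calls.reindex(columns=all_ind)
    calls_b = b.calls.iloc[keep_b].reset_index(drop=True).reindex(columns=all_ind)
    calls = pd.concat([calls_a, calls_b], ignore_index=True)
    return GenotypeTable(variants, calls)


def assign_allele_frequency(
    freqs: Mapping[str, float | None],
    order: Sequence[str] = FREQUENCY_SOURCE_ORDER,
    floor: float = 1e-3,
) -> float:
    """First populated frequency in priority order, else the configured floor.

    The default order prefers GnomAD NFE, then ExAC NFE, then 1000 Genomes
    EUR.  Values outside [0, 1] are rejected.
    """
    for src in order:
        v = freqs.get(src)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"frequency {v} from {src} outside [0, 1]")
        return float(v)
    return float(floor)


class SummaryStatsTable:
    """External-cohort association p-values keyed by normalized VariantKey.

    Absent keys are distinguishable from present ones: ``pvalues`` returns
    only the cohorts in which the key was tested.
    """

    def __init__(self, records: Mapping[VariantKey, Mapping[str, float]] | None = None):
        self._records: dict[VariantKey, dict[str, float]] = {}
        if records:
            for key, per_cohort in records.items():
                for cohort, p in per_cohort.items():
                    self.add(key, cohort, p)

    def add(self, key: VariantKey, cohort: str, p: float) -> None:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p} outside (0, 1] for {key}")
        self._records.setdefault(key, {})[cohort] = float(p)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._records

    def pvalues(self, key: VariantKey) -> dict[str, float]:
        """Cohort -> p for the cohorts where ``key`` is present (may be empty)."""
        return dict(self._records.get(key, {}))

    @property
    def cohorts(self) -> list[str]:
        out: list[str] = []
        for per in self._records.values():
            for c in per:
                if c not in out:
                    out.append(c)
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SummaryStatsTable":
        df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
        table = cls()
        for r in df.itertuples():
            key = normalize_variant_key(str(r.CHROM), int(r.POS), str(r.REF), str(r.ALT))
            table.add(key, str(r.COHORT), float(r.P))
        return table

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (k.chrom, k.pos, k.ref, k.alt, p, cohort)
            for k, per in self._records.items()
            for cohort, p in per.items()
        ]
        pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT", "P", "COHORT"]).to_csv(
            path, sep="\t", index=False
        )


def vcf_to_genotype_table(
    path: str | Path,
    samples: Sequence[str] | None = None,
    gmap: GeneticMap | None = None,
    af_floor: float = 1e-3,
) -> GenotypeTable:
    """Convert a VCF 4.x file with GT fields into a GenotypeTable.

    Multi-allelic records are split into one biallelic row per alternate
    allele; keys are normalized.  AF is taken from the INFO AF field when
    present, else left as the configured floor; CM is interpolated from
    ``gmap`` when given, else 0.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    use = list(samples) if samples is not None else list(vf.header.samples)
    var_rows, call_rows = [], []
    for rec in vf:
        alts = rec.alts or ()
        infos_af = rec.info.get("AF") if "AF" in rec.info else None
        for ai, alt in enumerate(alts):
            if alt is None or alt.startswith("<"):
                continue
            key = normalize_variant_key(rec.chrom, rec.pos, rec.ref, alt)
            af = float(infos_af[ai]) if infos_af is not None else af_floor
            cm = gmap.interpolate(key.chrom, key.pos) if gmap is not None else 0.0
            var_rows.append((key.chrom, key.pos, key.ref, key.alt, af, cm))
            calls = []
            allele_index = ai + 1
            for s in use:
                gt = rec.samples[s].get("GT")
                if gt is None or any(g is None for g in gt):
                    calls.append(np.nan)
                else:
                    calls.append(float(sum(1 for g in gt if g == allele_index)))
            call_rows.append(calls)
    variants = pd.DataFrame(var_rows, columns=_VARIANT_COLS)
    calls = pd.DataFrame(call_rows, columns=use, dtype=float)
    return GenotypeTable(variants, calls)
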