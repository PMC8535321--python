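"""Kinship-adjusted gene-based burden testing across multiplex families.

Qualifying rare variants in a gene are collapsed into a per-subject
burden b_i = sum_v w_v * dosage_iv and compared between affected and
unaffected subjects with a score test whose null variance accounts for
within-family genotype covariance through the pedigree kinship matrix:

    U = sum_i (y_i - ybar) b_i
    V = (sum_v w_v^2 * 2 p_v (1 - p_v)) * c' (2 Phi) c,   c = y - ybar
    stat = U / sqrt(V),   p two-sided normal

A positive statistic means rare functional variants are enriched in
affected subjects.  Allele frequencies p_v are estimated from one
randomly chosen member per family to avoid kinship-inflated estimates.
Genes with a single qualifying variant are reported descriptively, not
tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import block_diag
from scipy.stats import norm

from .pedigree import Pedigree, kinship_matrix

__all__ = [
    "FamilyCohort",
    "BurdenResult",
    "collapse_per_family",
    "gene_burden_test",
    "singleton_report",
    "burden_table",
]


@dataclass(frozen=True)
class BurdenResult:
    gene: str
    n_variants: int
    stat: float
    p: float
    tested: bool = True


class FamilyCohort:
    """Multiplex families plus unrelated subjects with per-gene dosages.

    ``families``: list of pedigrees (a singleton pedigree models an
    unrelated subject).  ``genotypes``: variant-by-individual dosage frame
    whose index is the variant label.  ``variant_gene``: variant label ->
    gene symbol.  Phenotype is taken from pedigree affection status
    (affected = 1, unaffected = 0; unknown members are excluded from
    testing).
    """

    def __init__(
        self,
        families: Sequence[Pedigree],
        genotypes: pd.DataFrame,
        variant_gene: Mapping[str, str],
    ):
        self.families = list(families)
        ids = [m.id for ped in self.families for m in ped]
        if len(ids) != len(set(ids)):
            raise ValueError("individual ids must be unique across families")
        self.genotypes = genotypes
        self.variant_gene = dict(variant_gene)
        missing = [v for v in genotypes.index if v not in self.variant_gene]
        if missing:
            raise ValueError(f"variants without a gene assignment: {missing[:5]}")
        self.subjects = [i for i in ids if i in genotypes.columns]

    @cached_property
    def family_of(self) -> dict[str, str]:
        return {
            m.id: ped.family_id for ped in self.families for m in ped
        }

    @cached_property
    def phenotype(self) -> pd.Series:
        status = {}
        for ped in self.families:
            for m in ped:
                if m.affected == "yes":
                    status[m.id] = 1.0
                elif m.affected == "no":
                    status[m.id] = 0.0
        return pd.Series(
            {i: status[i] for i in self.subjects if i in status}, dtype=float
        )

    @cached_property
    def kinship2(self) -> pd.DataFrame:
        """Block-diagonal 2*Phi over the tested subjects."""
        blocks, order = [], []
        for ped in self.families:
            K = kinship_matrix(ped)
            keep = [i for i in K.index if i in set(self.phenotype.index)]
            blocks.append(2.0 * K.loc[keep, keep].to_numpy())
            order.extend(keep)
        M = block_diag(*[b for b in blocks if b.size])
        return pd.DataFrame(M, index=order, columns=order).loc[
            self.phenotype.index, self.phenotype.index
        ]

    @cached_property
    def _gene_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for v in self.genotypes.index:
            out.setdefault(self.variant_gene[v], []).append(v)
        return out

    def gene_variants(self, gene: str) -> list[str]:
        return list(self._gene_map.get(gene, []))

    @property
    def genes(self) -> list[str]:
        return list(self._gene_map)


def collapse_per_family(
    carriers: Iterable[Mapping[str, str | None]],
) -> dict[str, int]:
    """One-subject-per-family collapsing of a carrier list.

    Each carrier record has ``individual``, ``family`` (None or "unrelated"
    for singletons) and ``status`` ("affected"/"unaffected").  Every family
    contributes at most one counted subject: counted as an MS family if any
    of its carriers is affected; unrelated unaffected carriers count once
    each as control subjects; unaffected relatives of an already-counted
    family are not double-counted.

    Returns ``{"n_ms_families": ..., "n_control_subjects": ...}``.
    """
    fam_status: dict[str, bool] = {}
    n_unrelated = 0
    for k, rec in enumerate(carriers):
        fam = rec.get("family")
        status = rec["status"]
        if status not in ("affected", "unaffected"):
            raise ValueError(f"invalid carrier status {status!r}")
        if fam in (None, "", "unrelated"):
            if status == "affected":
                fam_status[f"__singleton{k}"] = True
            else:
                n_unrelated += 1
        else:
            fam_status[fam] = fam_status.get(fam, False) or status == "affected"
    n_ms = sum(1 for aff in fam_status.values() if aff)
    n_ctrl = n_unrelated + sum(1 for aff in fam_status.values() if not aff)
    return {"n_ms_families": n_ms, "n_control_subjects": n_ctrl}


def _allele_freqs_one_per_family(
    cohort: FamilyCohort, variants: Sequence[str], rng: np.random.Generator
) -> np.ndarray:
    reps = []
    pheno_ids = set(cohort.phenotype.index)
    for ped in cohort.families:
        members = [m.id for m in ped if m.id in pheno_ids]
        if members:
            reps.append(members[int(rng.integers(len(members)))])
    G = cohort.genotypes.loc[variants, reps]
    return np.clip(G.mean(axis=1).to_numpy() / 2.0, 0.0, 1.0)


def gene_burden_test(
    cohort: FamilyCohort,
    gene: str,
    weights: Mapping[str, float] | None = None,
    madsen_browning: bool = False,
    seed: int = 0,
    allele_freqs: Mapping[str, float] | None = None,
) -> BurdenResult:
    """Kinship-adjusted score test for one gene.

    Default weights are 1 per variant (plain allele count);
    ``madsen_browning`` switches to 1/sqrt(2 p (1-p)) frequency weights.
    ``allele_freqs`` supplies known per-variant frequencies, bypassing the
    one-member-per-family estimate.  Genes with fewer than two qualifying
    variants are not tested (see :func:`singleton_report`).  A gene with
    no dosage variation is reported with stat 0, p 1 and flagged untested.
    """
    variants = cohort.gene_variants(gene)
    if len(variants) < 2:
        raise ValueError(
            f"{gene}: {len(variants)} qualifying variant(s); burden test needs >= 2"
        )
    rng = np.random.default_rng(seed)
    pheno = cohort.phenotype
    subjects = list(pheno.index)
    G = cohort.genotypes.loc[variants, subjects].to_numpy(dtype=float)
    G = np.nan_to_num(G, nan=0.0)
    if allele_freqs is not None:
        p_hat = np.array([allele_freqs[v] for v in variants], dtype=float)
    else:
        p_hat = _allele_freqs_one_per_family(cohort, variants, rng)
    if weights is not None:
        w = np.array([weights[v] for v in variants], dtype=float)
    elif madsen_browning:
        denom = np.sqrt(np.maximum(2.0 * p_hat * (1.0 - p_hat), 1e-12))
        w = 1.0 / denom
    else:
        w = np.ones(len(variants))
    b = w @ G
    c = pheno.to_numpy() - pheno.mean()
    U = float(c @ b)
    var_geno = float(np.sum(w ** 2 * 2.0 * p_hat * (1.0 - p_hat)))
    K2 = cohort.kinship2.to_numpy()
    V = var_geno * float(c @ K2 @ c)
    if V <= 0.0:
        return BurdenResult(gene, len(variants), 0.0, 1.0, tested=False)
    stat = U / math.sqrt(V)
    return BurdenResult(gene, len(variants), float(stat), float(2.0 * norm.sf(abs(stat))))


def singleton_report(cohort: FamilyCohort, gene: str) -> dict | None:
    """Descriptive record for a gene with exactly one qualifying variant.

    Carrier counts use the one-subject-per-family collapsing rule; no test
    statistic is computed.  Returns None for genes with no variant.
    """
    variants = cohort.gene_variants(gene)
    if not variants:
        return None
    if len(variants) != 1:
        raise ValueError(f"{gene} has {len(variants)} variants; expected exactly 1")
    v = variants[0]
    dos = cohort.genotypes.loc[v]
    aff = {i: s for i, s in cohort.phenotype.items()}
    records = []
    for iid, d in dos.items():
        if pd.isna(d) or d <= 0 or iid not in aff:
            continue
        fam = cohort.family_of.get(iid)
        is_singleton = (
            fam is not None
            and sum(1 for f in cohort.family_of.values() if f == fam) == 1
        )
        records.append(
            {
                "individual": iid,
                "family": "unrelated" if is_singleton else fam,
                "status": "affected" if aff[iid] == 1.0 else "unaffected",
            }
        )
    counts = collapse_per_family(records)
    return {"gene": gene, "variant": v, **counts}


def burden_table(
    cohort: FamilyCohort, genes: Sequence[str] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Burden results for all (or the given) multi-variant genes, sorted by p."""
    rows = []
    for gene in genes if genes is not None else cohort.genes:
        variants = cohort.gene_variants(gene)
        if len(variants) < 2:
            continue
        r = gene_burden_test(cohort, gene, seed=seed)
        rows.append((r.gene, r.n_variants, r.stat, r.p, r.tested))
    return (
        pd.DataFrame(rows, columns=["GENE", "N_VARIANTS", "BURDEN", "P", "TESTED"])
        .sort_values("P")
        .reset_index(drop=True)
    )
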