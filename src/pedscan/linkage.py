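"""Exact single-family non-parametric linkage analysis.

The engine enumerates the full inheritance-vector space of a pedigree
(two meiosis bits per non-founder, Lander-Green style), scores every
vector with the Whittemore-Halpern NPL-all allele-sharing statistic,
normalizes it exactly under the uniform null, and converts posterior
vector distributions at each marker into a Kong & Cox exponential-model
LOD score (exLOD) with its one-sided tail probability.

Multipoint analysis runs a hidden Markov chain over inheritance vectors
with per-meiosis transition probability given by the Haldane
recombination fraction of the inter-marker cM gap; forward-backward
yields the per-marker posterior that feeds the Kong & Cox computation.

Linkage regions are called from the resulting track by the peak/shore
rule: peaks are variants reaching the track maximum, shores extend to
the nearest variant where the exLOD drops to zero.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from math import factorial
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .io import GenotypeTable, VariantKey, chrom_sort_key, haldane_theta
from .pedigree import Pedigree, kinship_matrix  # re-export kinship_matrix

__all__ = [
    "FamilyLinkage",
    "KongCoxResult",
    "LinkageRegion",
    "kinship_matrix",
    "s_all",
    "npl_normalize",
    "genotype_vector_likelihood",
    "kong_cox_exlod",
    "multipoint_npl",
    "call_linkage_regions",
    "kong_cox_p",
]

LN10 = math.log(10.0)


def kong_cox_p(exlod: float) -> float:
    """One-sided tail probability of an exponential-model LOD score.

    p = 1 - Phi(sqrt(2 ln10 * exLOD)); an exLOD of 0 maps to p = 0.5.
    """
    if exlod < 0:
        raise ValueError("exLOD must be >= 0")
    return float(norm.sf(math.sqrt(2.0 * LN10 * exlod)))


@dataclass(frozen=True)
class KongCoxResult:
    delta_hat: float
    exlod: float
    p: float


@dataclass(frozen=True)
class LinkageRegion:
    chrom: str
    start: int  # 1-based inclusive, position of the left shore variant
    end: int    # 1-based inclusive, position of the right shore variant
    peak_positions: tuple[int, ...]
    max_exlod: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class FamilyLinkage:
    """Inheritance-vector enumeration and NPL scoring for one pedigree.

    Bit layout: non-founders in parents-first order, two bits each
    (paternal meiosis then maternal meiosis); bit value 0 transmits the
    parent's own paternal allele, 1 the maternal one.  Founder alleles are
    labelled 2f and 2f+1 in founder order.
    """

    def __init__(self, ped: Pedigree, bits_cap: int = 24):
        if len(ped.affected_ids) < 2:
            raise ValueError("NPL analysis needs >= 2 affected members")
        self.ped = ped
        self.founders = ped.founders
        self.nonfounders = ped.nonfounders
        self.bits = 2 * len(self.nonfounders)
        if self.bits > bits_cap:
            raise ValueError(
                f"{self.bits} meiosis bits exceed the enumeration cap {bits_cap}"
            )
        self.n_vectors = 1 << self.bits
        self._founder_slot = {f.id: i for i, f in enumerate(self.founders)}
        self.n_slots = 2 * len(self.founders)
        self._build_allele_labels()
        self._score_vectors()
        self._emission_tables: dict | None = None
        self._exp_grid: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    # -- inheritance-vector geometry -------------------------------------

    def _build_allele_labels(self) -> None:
        V = self.n_vectors
        vs = np.arange(V, dtype=np.uint32)
        labels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for f in self.founders:
            s = self._founder_slot[f.id]
            labels[f.id] = (
                np.full(V, 2 * s, dtype=np.uint8),
                np.full(V, 2 * s + 1, dtype=np.uint8),
            )
        for k, nf in enumerate(self.nonfounders):
            bp = (vs >> np.uint32(2 * k)) & 1
            bm = (vs >> np.uint32(2 * k + 1)) & 1
            fa = labels[nf.father_id]
            mo = labels[nf.mother_id]
            labels[nf.id] = (
                np.where(bp == 0, fa[0], fa[1]).astype(np.uint8),
                np.where(bm == 0, mo[0], mo[1]).astype(np.uint8),
            )
        self.allele_labels = labels

    def s_all_vector(self) -> np.ndarray:
        return self._s_all

    def _score_vectors(self) -> None:
        """NPL-all score of every vector and its exact null moments.

        S_all = 2^(-a) * sum over one-allele picks h of prod_f b_f(h)!
        where b_f counts how often founder allele f occurs in the pick.
        """
        aff = [self.ped.by_id[i] for i in self.ped.affected_ids]
        a = len(aff)
        V = self.n_vectors
        fact = np.array([factorial(c) for c in range(a + 1)], dtype=float)
        S = np.zeros(V)
        pair_labels = [self.allele_labels[m.id] for m in aff]
        for pick in itertools.product((0, 1), repeat=a):
            chosen = np.stack(
                [pair_labels[i][which] for i, which in enumerate(pick)], axis=0
            )
            term = np.ones(V)
            for lab in range(self.n_slots):
                cnt = (chosen == lab).sum(axis=0)
                term *= fact[cnt]
            S += term
        S /= 2.0 ** a
        self._s_all = S
        self.mu0 = float(S.mean())
        sigma0 = float(S.std())
        if sigma0 < 1e-12:
            warnings.warn("uninformative family: sigma0 = 0, all Z set to 0")
            self.sigma0 = 0.0
            self.Z = np.zeros(V)
        else:
            self.sigma0 = sigma0
            self.Z = (S - self.mu0) / sigma0

    def max_sharing_posterior(self) -> np.ndarray:
        """Uniform posterior over the vectors attaining the maximal NPL-all
        score: the fully informative, maximal-sharing configuration."""
        S = self._s_all
        mask = S >= S.max() - 1e-12
        return mask / mask.sum()

    # -- single-marker genotype likelihoods ------------------------------

    def _genotyped_with_calls(self, dosages: Mapping[str, float | None]):
        out = []
        for iid, d in dosages.items():
            if iid not in self.ped.by_id:
                raise KeyError(f"unknown individual {iid}")
            if d is None or (isinstance(d, float) and math.isnan(d)):
                continue
            if d not in (0, 1, 2):
                raise ValueError(f"dosage {d} for {iid} not in {{0,1,2}}")
            out.append((iid, int(d)))
        return out

    def _build_emission_tables(self) -> dict:
        """Bit-packed founder-assignment masks for fast marker likelihoods.

        For every individual and observed dosage d, a boolean mask over
        (vector, founder-allele assignment) marks the assignments implying
        that dosage under the vector.  Masks are packed into uint64 words;
        a marker likelihood is then a handful of gathers, ANDs and weighted
        popcounts.  Feasible when the founder-allele space 2^(2F) is small.
        """
        if self._emission_tables is not None:
            return self._emission_tables
        if self.n_slots > 14:
            raise ValueError("too many founder alleles for the packed fast path")
        X = 1 << self.n_slots
        W = (X + 63) // 64
        xb = ((np.arange(X, dtype=np.uint32)[:, None] >> np.arange(self.n_slots)) & 1).astype(
            np.uint8
        )  # (X, slots)
        altcount = xb.sum(axis=1)  # (X,)

        def pack(rows_bool: np.ndarray) -> np.ndarray:
            # rows_bool: (..., X) -> (..., W) uint64, little-endian bit order
            padded = np.zeros(rows_bool.shape[:-1] + (W * 64,), dtype=np.uint8)
            padded[..., :X] = rows_bool
            packed8 = np.packbits(padded, axis=-1, bitorder="little")
            return packed8.view(np.uint64)

        masks: dict[str, list[np.ndarray]] = {}
        for m in self.ped.members:
            a1, a2 = self.allele_labels[m.id]
            implied = xb[:, a1].T + xb[:, a2].T  # (V, X) dosage implied
            masks[m.id] = [pack(implied == d) for d in (0, 1, 2)]
        count_masks = [pack(altcount == k) for k in range(self.n_slots + 1)]
        self._emission_tables = {
            "masks": masks,
            "count_masks": count_masks,
            "W": W,
        }
        return self._emission_tables

    def marker_likelihood(
        self, dosages: Mapping[str, float | None], allele_freq: float
    ) -> np.ndarray:
        """P(observed dosages | inheritance vector) for every vector.

        Founder alleles are i.i.d. Bernoulli(allele_freq) for the alternate
        allele; the likelihood sums founder-allele assignments consistent
        with the vector and the observed calls.  Missing calls impose no
        constraint.
        """
        if not 0.0 < allele_freq < 1.0:
            raise ValueError(f"allele frequency {allele_freq} outside (0, 1)")
        obs = self._genotyped_with_calls(dosages)
        tab = self._build_emission_tables()
        acc = np.full((self.n_vectors, tab["W"]), ~np.uint64(0), dtype=np.uint64)
        for iid, d in obs:
            acc &= tab["masks"][iid][d]
        p = allele_freq
        lik = np.zeros(self.n_vectors)
        for k, km in enumerate(tab["count_masks"]):
            w = p ** k * (1.0 - p) ** (self.n_slots - k)
            if w == 0.0:
                continue
            lik += w * np.bitwise_count(acc & km[None, :]).sum(axis=1)
        return lik

    def marker_likelihood_by_coloring(
        self, dosages: Mapping[str, float | None], allele_freq: float
    ) -> np.ndarray:
        """Reference likelihood via per-vector constraint coloring.

        Independent of the packed fast path: for each vector the observed
        dosages impose equality (dosage 0 or 2) or inequality (dosage 1)
        constraints on founder-allele slots; the likelihood factorizes over
        the resulting components.  Slow but exact; used as a cross-check and
        as a fallback for pedigrees with many founders.
        """
        if not 0.0 < allele_freq < 1.0:
            raise ValueError(f"allele frequency {allele_freq} outside (0, 1)")
        obs = self._genotyped_with_calls(dosages)
        p, q = allele_freq, 1.0 - allele_freq
        n = self.n_slots
        lik = np.zeros(self.n_vectors)
        labels = self.allele_labels
        for v in range(self.n_vectors):
            # union-find with parity (inequality edges), plus fixed values
            parent = list(range(n))
            parity = [0] * n  # parity relative to parent
            fixed: dict[int, int] = {}  # root -> value of root

            def find(x: int) -> tuple[int, int]:
                par = 0
                while parent[x] != x:
                    par ^= parity[x]
                    x = parent[x]
                return x, par

            ok = True
            for iid, d in obs:
                s1 = int(labels[iid][0][v])
                s2 = int(labels[iid][1][v])
                if d == 1:
                    if s1 == s2:
                        ok = False
                        break
                    r1, p1 = find(s1)
                    r2, p2 = find(s2)
                    if r1 == r2:
                        if p1 == p2:  # forced equal but must differ
                            ok = False
                            break
                    else:
                        parent[r1] = r2
                        parity[r1] = p1 ^ p2 ^ 1
                        if r1 in fixed:
                            val = fixed.pop(r1) ^ parity[r1]
                            if fixed.setdefault(r2, val) != val:
                                ok = False
                                break
                else:
                    val = d // 2
                    for s in (s1, s2):
                        r, par = find(s)
                        want = val ^ par
                        if fixed.setdefault(r, want) != want:
                            ok = False
                            break
                    if not ok:
                        break
            if not ok:
                continue
            comp_sizes: dict[int, list[int]] = {}
            for s in range(n):
                r, par = find(s)
                comp_sizes.setdefault(r, [0, 0])[par] += 1
            total = 1.0
            for r, (n0, n1) in comp_sizes.items():
                if r in fixed:
                    if fixed[r] == 1:
                        n0, n1 = n1, n0
                    total *= q ** n0 * p ** n1
                else:
                    total *= q ** n0 * p ** n1 + p ** n0 * q ** n1
            lik[v] = total
        return lik

    # -- Kong & Cox exponential model ------------------------------------

    def _exp_grid_tables(self, delta_max: float, n_grid: int):
        if self._exp_grid is not None and len(self._exp_grid[0]) == n_grid:
            return self._exp_grid
        deltas = np.linspace(0.0, delta_max, n_grid)
        expdz = np.exp(np.outer(deltas, self.Z - self.Z.max()))  # stable
        log_e0 = (
            np.log(expdz.mean(axis=1)) + deltas * self.Z.max()
        )  # log E0[e^{dZ}]
        self._exp_grid = (deltas, expdz, log_e0)
        return self._exp_grid

    def kong_cox(
        self,
        weights: np.ndarray,
        delta_max: float = 10.0,
        tol: float = 1e-6,
    ) -> KongCoxResult:
        """Maximize the exponential-tilting likelihood ratio over delta >= 0.

        L(delta) = sum_v w(v) e^{delta Z(v)} / E0[e^{delta Z}].  A coarse
        grid brackets the maximum, golden-section search refines it; when
        the maximizer sits at the search boundary the analytic supremum
        sum_{v in argmax Z} w(v) / P0(argmax Z) is reported instead, which
        is the delta -> infinity limit.
        """
        w = np.asarray(weights, dtype=float)
        if not np.all(np.isfinite(w)) or w.sum() <= 0:
            raise ValueError("posterior weights must be finite with positive mass")
        w = w / w.sum()
        Z = self.Z
        mean_z = float(w @ Z)
        if mean_z <= 1e-12 or self.sigma0 == 0.0:
            return KongCoxResult(0.0, 0.0, 0.5)

        zmax = Z.max()
        logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)

        def log10_lr(delta: float) -> float:
            lw = logsumexp(logw + delta * Z)
            l0 = logsumexp(delta * Z) - math.log(self.n_vectors)
            return (lw - l0) / LN10

        deltas, expdz, log_e0 = self._exp_grid_tables(delta_max, 33)
        grid_lw = np.log(expdz @ w) + deltas * zmax
        grid_f = (grid_lw - log_e0) / LN10
        i = int(np.argmax(grid_f))
        lo = deltas[max(i - 1, 0)]
        hi = deltas[min(i + 1, len(deltas) - 1)]
        # golden-section search on [lo, hi]
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = log10_lr(c), log10_lr(d)
        while b - a > tol:
            if fc >= fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = log10_lr(c)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = log10_lr(d)
        delta_hat = 0.5 * (a + b)
        f_hat = log10_lr(delta_hat)
        if delta_hat >= delta_max - 1e-3:
            top = Z >= zmax - 1e-12
            w_top = float(w[top].sum())
            if w_top > 0:
                f_inf = (math.log(w_top) - math.log(top.sum() / self.n_vectors)) / LN10
                if f_inf > f_hat:
                    f_hat = f_inf
                    delta_hat = math.inf
        exlod = max(f_hat, 0.0)
        if exlod == 0.0:
            delta_hat = 0.0
        return KongCoxResult(float(delta_hat), float(exlod), kong_cox_p(exlod))

    # -- multipoint chain -------------------------------------------------

    def _apply_transition(self, prob: np.ndarray, theta: float) -> np.ndarray:
        """One inter-marker step of the inheritance-vector Markov chain.

        Each meiosis bit flips independently with probability theta; the
        transition factorizes over bits, so it is applied axis by axis on
        the (2,)*bits tensor view.
        """
        if theta <= 0.0:
            return prob
        t = prob.reshape((2,) * self.bits)
        for axis in range(self.bits):
            t = (1.0 - theta) * t + theta * np.flip(t, axis=axis)
        return t.reshape(-1)

    def multipoint_posteriors(
        self,
        markers: GenotypeTable,
        genotyped: Sequence[str] | None = None,
    ) -> list[np.ndarray]:
        """Per-marker posterior inheritance-vector distributions.

        ``markers`` must be sorted by position within a single chromosome;
        cM positions come from its CM column.  Only genotyped pedigree
        members with a call column are constrained.
        """
        ids = genotyped if genotyped is not None else self.ped.genotyped_ids
        ids = [i for i in ids if i in markers.calls.columns]
        pos = markers.variants.POS.to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("markers must be ordered by position")
        cm = markers.variants.CM.to_numpy(dtype=float)
        M = markers.n_variants
        emis = []
        for j in range(M):
            dosages = {i: markers.calls[i].iat[j] for i in ids}
            emis.append(self.marker_likelihood(dosages, float(markers.variants.AF.iat[j])))
        thetas = [haldane_theta(max(cm[j + 1] - cm[j], 0.0)) for j in range(M - 1)]
        V = self.n_vectors
        alpha = [np.full(V, 1.0 / V)]
        for j in range(1, M):
            prev = alpha[j - 1] * emis[j - 1]
            s = prev.sum()
            if s <= 0:
                raise FloatingPointError(f"zero marker likelihood at index {j - 1}")
            alpha.append(self._apply_transition(prev / s, thetas[j - 1]))
        beta = [np.ones(V) for _ in range(M)]
        for j in range(M - 2, -1, -1):
            nxt = emis[j + 1] * beta[j + 1]
            s = nxt.sum()
            if s <= 0:
                raise FloatingPointError(f"zero marker likelihood at index {j + 1}")
            beta[j] = self._apply_transition(nxt / s, thetas[j])
        posts = []
        for j in range(M):
            post = alpha[j] * emis[j] * beta[j]
            s = post.sum()
            if s <= 0:
                raise FloatingPointError(f"zero posterior at marker index {j}")
            posts.append(post / s)
        return posts


# -- functional wrappers mirroring the operation surface -------------------


def s_all(ped: Pedigree, vector: int, engine: FamilyLinkage | None = None) -> float:
    """Whittemore-Halpern NPL-all score of one inheritance vector."""
    eng = engine or FamilyLinkage(ped)
    return float(eng.s_all_vector()[vector])


def npl_normalize(ped: Pedigree, engine: FamilyLinkage | None = None):
    """Exact null moments of S_all and the normalized per-vector Z.

    Returns (mu0, sigma0, Z) where Z has exact mean 0 and variance 1 over
    the uniform inheritance-vector distribution (unless the family is
    uninformative, in which case sigma0 = 0 and Z is all zeros).
    """
    eng = engine or FamilyLinkage(ped)
    return eng.mu0, eng.sigma0, eng.Z


def genotype_vector_likelihood(
    ped: Pedigree,
    dosages: Mapping[str, float | None],
    allele_freq: float,
    engine: FamilyLinkage | None = None,
) -> np.ndarray:
    """P(observed biallelic dosages | v) for every inheritance vector v."""
    eng = engine or FamilyLinkage(ped)
    return eng.marker_likelihood(dosages, allele_freq)


def kong_cox_exlod(
    engine: FamilyLinkage, weights: np.ndarray, delta_max: float = 10.0
) -> KongCoxResult:
    """Kong & Cox exponential-model LOD for a posterior vector distribution."""
    return engine.kong_cox(weights, delta_max=delta_max)


def multipoint_npl(
    ped: Pedigree,
    markers: GenotypeTable,
    genotyped: Sequence[str] | None = None,
    engine: FamilyLinkage | None = None,
    include_sex_chromosomes: bool = False,
) -> pd.DataFrame:
    """Multipoint NPL track: per-variant Z, exLOD and Kong & Cox p.

    Markers are processed per chromosome in genomic order.  Sex chromosomes
    are excluded by default (the autosomal inheritance model does not handle
    X transmission).  Returns a DataFrame with columns CHROM, POS, REF, ALT,
    CM, Z, EXLOD, P.
    """
    eng = engine or FamilyLinkage(ped)
    markers = markers.sort_genomic()
    rows = []
    for chrom, idx in markers.variants.groupby("CHROM", sort=False).groups.items():
        if not include_sex_chromosomes and str(chrom).removeprefix("chr") in {"X", "Y"}:
            continue
        sub = GenotypeTable(
            markers.variants.loc[idx], markers.calls.loc[idx]
        )
        posts = eng.multipoint_posteriors(sub, genotyped=genotyped)
        for j, post in enumerate(posts):
            res = eng.kong_cox(post)
            r = sub.variants.iloc[j]
            rows.append(
                (
                    str(r.CHROM),
                    int(r.POS),
                    str(r.REF),
                    str(r.ALT),
                    float(r.CM),
                    float(post @ eng.Z),
                    res.exlod,
                    res.p,
                )
            )
    return pd.DataFrame(
        rows, columns=["CHROM", "POS", "REF", "ALT", "CM", "Z", "EXLOD", "P"]
    )


def call_linkage_regions(
    track: pd.DataFrame, peak_tol: float = 1e-6
) -> list[LinkageRegion]:
    """Peak/shore region calling on an exLOD track.

    Peaks are variants within ``peak_tol`` of the track's global maximum.
    Each peak extends left and right to the nearest variant whose exLOD is
    <= 0 (that shore variant's position is the region endpoint; chromosome
    ends terminate regions).  Overlapping or shore-sharing regions on the
    same chromosome are merged.  An all-nonpositive track yields no regions.
    """
    if track.empty:
        return []
    max_exlod = float(track.EXLOD.max())
    if max_exlod <= 0.0:
        return []
    regions: list[LinkageRegion] = []
    for chrom, g in track.groupby("CHROM", sort=False):
        g = g.sort_values("POS").reset_index(drop=True)
        lods = g.EXLOD.to_numpy()
        pos = g.POS.to_numpy()
        peak_idx = np.flatnonzero(lods >= max_exlod - peak_tol)
        if peak_idx.size == 0:
            continue
        raw: list[tuple[int, int, list[int]]] = []
        for pi in peak_idx:
            left = pi
            while left > 0 and lods[left - 1] > 0:
                left -= 1
            if left > 0:
                left -= 1  # include the shore variant with exLOD <= 0
            right = pi
            n = len(lods)
            while right < n - 1 and lods[right + 1] > 0:
                right += 1
            if right < n - 1:
                right += 1
            raw.append((left, right, [pi]))
        raw.sort()
        merged: list[tuple[int, int, list[int]]] = []
        for lo, hi, peaks in raw:
            if merged and lo <= merged[-1][1]:
                mlo, mhi, mpeaks = merged[-1]
                merged[-1] = (mlo, max(mhi, hi), mpeaks + peaks)
            else:
                merged.append((lo, hi, peaks))
        for lo, hi, peaks in merged:
            regions.append(
                LinkageRegion(
                    chrom=str(chrom),
                    start=int(pos[lo]),
                    end=int(pos[hi]),
                    peak_positions=tuple(int(pos[p]) for p in sorted(set(peaks))),
                    max_exlod=max_exlod,
                )
            )
    regions.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start))
    return regions


def regions_to_frame(regions: Iterable[LinkageRegion]) -> pd.DataFrame:
    """BED-like (1-based inclusive) table of called regions."""
    return pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.max_exlod, len(r.peak_positions))
            for r in regions
        ],
        columns=["CHROM", "START", "END", "MAX_EXLOD", "N_PEAKS"],
    )
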