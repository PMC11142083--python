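"""Variance-components heritability and linkage analysis.

The trait y (one value per individual) is modelled as multivariate normal
with mean X beta and covariance

    V = 2*Phi * sigma2_g  +  Pi * sigma2_q  +  I * sigma2_e,

where Phi is pedigree kinship, Pi the locus-specific matrix of pairwise
proportions of alleles shared identical by descent, sigma2_g the additive
polygenic variance, sigma2_q the locus (QTL) variance and sigma2_e the
residual.  All fits are maximum likelihood (not REML) so that log-likelihoods
of nested models are directly comparable; the LOD score at a locus is
(lnL_H1 - lnL_H0) / ln 10 with sigma2_q constrained non-negative, hence
LOD >= 0.

The likelihood factorises over families, which this module exploits twice:
computationally (families are processed as stacked blocks, grouped by size,
with batched Cholesky factorisations) and statistically (per-family LOD
contributions evaluated at the shared parameter estimates sum exactly to the
total LOD, the additive decomposition behind linkage-enriched family
selection).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .pedigree import KinshipMatrix

logger = logging.getLogger(__name__)

_LN10 = float(np.log(10.0))
_LOGLIK_TOL = 1e-8

__all__ = [
    "IBDMatrix",
    "VarianceComponents",
    "PolygenicFit",
    "LocusFit",
    "LinkageScan",
    "FamilyLOD",
    "IdentifiabilityError",
    "fit_polygenic",
    "lod_scan",
    "family_lods",
    "select_linked_families",
    "support_interval",
    "linkage_accounted",
]


class IdentifiabilityError(ValueError):
    """Variance components cannot be separated for the given structure."""


@dataclass
class IBDMatrix:
    """Pairwise proportion of alleles shared IBD at one locus."""

    chrom: str
    pos: int
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("IBD matrix shape does not match ids")
        if np.nanmin(self.values) < -1e-9 or np.nanmax(self.values) > 1.0 + 1e-9:
            raise ValueError("IBD proportions must lie in [0, 1]")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("IBD matrix must be symmetric")

    def reindex(self, ids) -> np.ndarray:
        pos = {iid: k for k, iid in enumerate(self.ids)}
        try:
            idx = np.array([pos[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in IBD matrix") from exc
        return self.values[np.ix_(idx, idx)]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_q: float
    sigma2_e: float

    @property
    def total(self) -> float:
        return self.sigma2_g + self.sigma2_q + self.sigma2_e


@dataclass
class PolygenicFit:
    components: VarianceComponents
    beta: np.ndarray
    loglik: float
    h2: float
    h2_se: float
    h2_p: float
    n: int
    # internal: variance ratio a = sigma2_g / sigma2_e for warm starts
    a: float = field(repr=False, default=0.0)


@dataclass
class LocusFit:
    chrom: str
    pos: int
    lod: float
    loglik_h1: float
    components: VarianceComponents
    beta: np.ndarray = field(repr=False, default=None)


@dataclass
class LinkageScan:
    loci: list[LocusFit]
    loglik_h0: float
    null_fit: PolygenicFit

    @property
    def peak(self) -> LocusFit:
        if not self.loci:
            raise ValueError("empty scan")
        return max(self.loci, key=lambda l: l.lod)

    @property
    def peak_lod(self) -> float:
        return self.peak.lod


@dataclass
class FamilyLOD:
    family_id: str
    pedlod: float
    n_members: int


# ---------------------------------------------------------------------------
# family-block likelihood machinery


class FamilyBlocks:
    """Trait, design and relationship matrices split into family blocks.

    Families are grouped by size so that Cholesky factorisations and solves
    run batched over same-size stacks.  Beta is shared across families and
    profiled out by generalised least squares; the residual scale sigma2_e is
    profiled analytically, leaving the variance ratios a = sigma2_g/sigma2_e
    and b = sigma2_q/sigma2_e as the free parameters.
    """

    def __init__(self, y, X, kinship, families=None):
        y = np.asarray(y, dtype=float)
        if isinstance(kinship, KinshipMatrix):
            kin2 = kinship.kin2
            if families is None:
                families = kinship.families
        else:
            kin2 = 2.0 * np.asarray(kinship, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = len(y)
        if X.shape[0] != n or kin2.shape != (n, n):
            raise ValueError("y, X and kinship are not conformable")
        if np.any(np.isnan(y)) or np.any(np.isnan(X)):
            raise ValueError("missing values in trait or design")
        if families is None:
            families = _connected_components(kin2)
        families = np.asarray(families, dtype=object)
        self.n, self.p = n, X.shape[1]
        self.y, self.X = y, X

        fam_order: list = []
        idx_by_fam: dict = {}
        for i, f in enumerate(families):
            if f not in idx_by_fam:
                idx_by_fam[f] = []
                fam_order.append(f)
            idx_by_fam[f].append(i)
        self.family_ids = fam_order
        self.family_sizes = {f: len(idx_by_fam[f]) for f in fam_order}

        # group same-size families into stacks
        self.groups: list[dict] = []
        by_size: dict[int, list] = {}
        for f in fam_order:
            by_size.setdefault(len(idx_by_fam[f]), []).append(f)
        for size, fams in sorted(by_size.items()):
            idx = np.array([idx_by_fam[f] for f in fams], dtype=int)  # (F, m)
            K = kin2[idx[:, :, None], idx[:, None, :]]  # (F, m, m)
            self.groups.append(
                {
                    "size": size,
                    "families": fams,
                    "idx": idx,
                    "K": K,
                    "y": y[idx],
                    "X": X[idx],  # (F, m, p)
                    "I": np.broadcast_to(np.eye(size), K.shape).copy(),
                }
            )
        self.max_offdiag_kin = max(
            (
                float(np.max(np.abs(g["K"] - g["K"] * np.eye(g["size"]))))
                for g in self.groups
            ),
            default=0.0,
        )

    # -- core linear algebra --------------------------------------------------

    def gather(self, full_matrix: np.ndarray) -> list[np.ndarray]:
        """Split a full (n, n) matrix into per-group stacks aligned with K."""
        out = []
        for g in self.groups:
            idx = g["idx"]
            out.append(full_matrix[idx[:, :, None], idx[:, None, :]])
        return out

    def with_design(self, X_new: np.ndarray) -> "FamilyBlocks":
        """Same families and relationships, different fixed-effect design."""
        clone = object.__new__(FamilyBlocks)
        clone.__dict__.update(self.__dict__)
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[:, None]
        clone.X = X_new
        clone.p = X_new.shape[1]
        clone.groups = [dict(g, X=X_new[g["idx"]]) for g in self.groups]
        return clone

    def _factor(self, a: float, b: float, pis) -> list[tuple]:
        """Cholesky factors of R = I + a*2Phi + b*Pi per group."""
        out = []
        for gi, g in enumerate(self.groups):
            R = g["I"] + a * g["K"]
            if b != 0.0 and pis is not None:
                R = R + b * pis[gi]
            L = np.linalg.cholesky(R)
            out.append(L)
        return out

    def profile_loglik(self, a: float, b: float = 0.0, pis=None):
        """Maximised log-likelihood over (beta, scale) at variance ratios
        (a, b); returns (loglik, beta, sigma2_e, logdet)."""
        try:
            Ls = self._factor(a, b, pis)
        except np.linalg.LinAlgError:
            return -np.inf, None, np.nan, np.nan
        p = self.p
        M = np.zeros((p + 1, p + 1))
        logdet = 0.0
        for g, L in zip(self.groups, Ls):
            logdet += 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
            Z = np.concatenate([g["X"], g["y"][:, :, None]], axis=2)
            U = np.linalg.solve(L, Z)  # batched forward substitution
            M += np.einsum("fmi,fmj->ij", U, U)
        XtRX, XtRy, ytRy = M[:p, :p], M[:p, p], M[p, p]
        try:
            beta = np.linalg.solve(XtRX, XtRy)
        except np.linalg.LinAlgError:
            raise ValueError("rank-deficient fixed-effect design") from None
        rss = float(ytRy - beta @ XtRy)
        if rss <= 0:
            rss = np.finfo(float).tiny
        sigma2 = rss / self.n
        ll = -0.5 * (self.n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
        return float(ll), beta, float(sigma2), float(logdet)

    def loglik_at(self, sigma2_g: float, sigma2_e: float, sigma2_q: float = 0.0, pis=None) -> float:
        """Log-likelihood at explicit variance components (beta profiled)."""
        if sigma2_e <= 0:
            return -np.inf
        a, b = sigma2_g / sigma2_e, sigma2_q / sigma2_e
        try:
            Ls = self._factor(a, b, pis)
        except np.linalg.LinAlgError:
            return -np.inf
        p = self.p
        M = np.zeros((p + 1, p + 1))
        logdet = 0.0
        for g, L in zip(self.groups, Ls):
            logdet += 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
            Z = np.concatenate([g["X"], g["y"][:, :, None]], axis=2)
            U = np.linalg.solve(L, Z)
            M += np.einsum("fmi,fmj->ij", U, U)
        beta = np.linalg.solve(M[:p, :p], M[:p, p])
        rss = float(M[p, p] - beta @ M[:p, p])
        return float(
            -0.5 * (self.n * np.log(2 * np.pi * sigma2_e) + logdet + rss / sigma2_e)
        )

    def family_logliks(
        self, a: float, b: float, beta: np.ndarray, sigma2: float, pis=None
    ) -> dict:
        """Per-family log-likelihood contributions at fixed parameters."""
        Ls = self._factor(a, b, pis)
        out = {}
        for g, L in zip(self.groups, Ls):
            r = g["y"] - np.einsum("fmp,p->fm", g["X"], beta)
            u = np.linalg.solve(L, r[:, :, None])[:, :, 0]
            quad = (u**2).sum(axis=1)
            ld = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
            m = g["size"]
            lls = -0.5 * (m * np.log(2 * np.pi * sigma2) + ld + quad / sigma2)
            for f, ll in zip(g["families"], lls):
                out[f] = float(ll)
        return out

    def gls_cov(self, a: float, b: float = 0.0, pis=None):
        """GLS beta, its covariance (d.o.f.-corrected residual variance) and
        the profiled loglik at the given variance ratios."""
        ll, beta, sigma2_ml, _ = self.profile_loglik(a, b, pis)
        Ls = self._factor(a, b, pis)
        p = self.p
        XtRX = np.zeros((p, p))
        for g, L in zip(self.groups, Ls):
            U = np.linalg.solve(L, g["X"])
            XtRX += np.einsum("fmi,fmj->ij", U, U)
        dof = max(self.n - p, 1)
        s2 = sigma2_ml * self.n / dof
        cov = s2 * np.linalg.inv(XtRX)
        return beta, cov, ll, sigma2_ml


def _connected_components(kin2: np.ndarray) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = csr_matrix(np.abs(kin2) > 1e-12)
    _, labels = connected_components(adj, directed=False)
    return labels.astype(object)


# ---------------------------------------------------------------------------
# fitting


def _maximize(blocks: FamilyBlocks, pis=None, a_start: float = 0.5, with_qtl: bool = False):
    """Maximise the profiled log-likelihood over the variance ratios.

    Bounded quasi-Newton from a handful of fixed starts; with_qtl adds the
    ratio b >= 0 for the locus component.  Returns (a, b, loglik, beta,
    sigma2_e).  With a QTL the search starts at (a_start, 0), i.e. exactly at
    the polygenic null, so the achieved likelihood can never fall below it.
    """
    if with_qtl:
        starts = [
            (a_start, 0.0),
            (a_start, 0.25),
            (0.0, 0.5),
            (max(a_start * 0.5, 0.05), 1.0),
        ]
        bounds = [(0.0, 1e4), (0.0, 1e4)]
        fun = lambda t: -blocks.profile_loglik(t[0], t[1], pis)[0]
    else:
        starts = [(a_start,), (0.0,), (1.0,), (3.0,)]
        bounds = [(0.0, 1e4)]
        fun = lambda t: -blocks.profile_loglik(t[0], 0.0, None)[0]

    best = None
    for k, x0 in enumerate(starts):
        res = optimize.minimize(
            fun,
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        cand = (float(-res.fun), tuple(float(v) for v in res.x))
        if best is None or cand[0] > best[0] + 1e-12:
            best = cand
        if k == 0 and res.success:
            break  # fixed perturbed restarts only on non-convergence
    ll_best, theta = best
    # never report worse than the start point itself (guards LOD >= 0)
    ll_at_start = -fun(np.asarray(starts[0], dtype=float))
    if ll_at_start > ll_best:
        ll_best, theta = ll_at_start, starts[0]
    a = theta[0]
    b = theta[1] if with_qtl else 0.0
    ll, beta, sigma2, _ = blocks.profile_loglik(a, b, pis)
    return a, b, float(ll), beta, float(sigma2)


def fit_polygenic(y, X, kinship, families=None) -> PolygenicFit:
    """ML polygenic model: cov(y) = 2*Phi*sigma2_g + I*sigma2_e.

    Returns variance components, heritability h2 = sigma2_g / (sigma2_g +
    sigma2_e), its delta-method standard error from the inverse observed
    information, and a likelihood-ratio p-value for h2 = 0 against the
    boundary null (an equal mixture of chi2_0 and chi2_1).
    """
    blocks = FamilyBlocks(y, X, kinship, families)
    if blocks.max_offdiag_kin < 1e-12:
        raise IdentifiabilityError(
            "all individuals mutually unrelated (2*Phi = I): "
            "sigma2_g and sigma2_e are confounded"
        )
    a, _, ll, beta, sigma2_e = _maximize(blocks, with_qtl=False)
    sigma2_g = a * sigma2_e
    h2 = sigma2_g / (sigma2_g + sigma2_e)

    ll0 = blocks.profile_loglik(0.0, 0.0, None)[0]
    lrt = max(0.0, 2.0 * (ll - ll0))
    h2_p = 1.0 if lrt <= 0 else 0.5 * float(stats.chi2.sf(lrt, df=1))

    h2_se = _h2_se(blocks, sigma2_g, sigma2_e)
    return PolygenicFit(
        components=VarianceComponents(sigma2_g, 0.0, sigma2_e),
        beta=beta,
        loglik=ll,
        h2=float(h2),
        h2_se=h2_se,
        h2_p=h2_p,
        n=blocks.n,
        a=a,
    )


def _h2_se(blocks: FamilyBlocks, sg2: float, se2: float) -> float:
    """Delta-method SE of h2 from a numerical observed-information matrix in
    (sigma2_g, sigma2_e).  NaN at the h2 = 0 boundary, where the usual
    asymptotics do not apply."""
    if sg2 <= 1e-10:
        return float("nan")
    theta = np.array([sg2, se2])
    h = 1e-4 * np.maximum(np.abs(theta), 1e-3)

    def f(t):
        return blocks.loglik_at(t[0], t[1])

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float("nan")
    tot = sg2 + se2
    grad = np.array([se2 / tot**2, -sg2 / tot**2])
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var > 0 else float("nan")


def lod_scan(y, X, kinship, ibd: list[IBDMatrix], families=None, ids=None) -> LinkageScan:
    """LOD scan over a list of per-locus IBD matrices.

    H0 is the polygenic model; at each locus H1 adds Pi*sigma2_q with
    sigma2_q >= 0.  LOD = (lnL_H1 - lnL_H0)/ln 10, clamped at 0 by the
    boundary constraint.  ``ids`` gives the individual order of y/X (defaults
    to the kinship ids when a KinshipMatrix is passed).
    """
    blocks = FamilyBlocks(y, X, kinship, families)
    if ids is None:
        if not isinstance(kinship, KinshipMatrix):
            raise ValueError("pass ids= when kinship is a bare matrix")
        ids = kinship.ids
    null = fit_polygenic(y, X, kinship, families)
    loci: list[LocusFit] = []
    for mat in ibd:
        pis = blocks.gather(mat.reindex(ids))
        a, b, ll1, beta, sigma2_e = _maximize(
            blocks, pis=pis, a_start=null.a, with_qtl=True
        )
        if ll1 < null.loglik:  # numerically impossible by construction; guard anyway
            ll1, a, b = null.loglik, null.a, 0.0
            beta, sigma2_e = null.beta, null.components.sigma2_e
        lod = max(0.0, (ll1 - null.loglik) / _LN10)
        loci.append(
            LocusFit(
                chrom=mat.chrom,
                pos=mat.pos,
                lod=lod,
                loglik_h1=ll1,
                components=VarianceComponents(a * sigma2_e, b * sigma2_e, sigma2_e),
                beta=beta,
            )
        )
    return LinkageScan(loci=loci, loglik_h0=null.loglik, null_fit=null)


def family_lods(
    y, X, kinship, ibd_at_peak: IBDMatrix, scan: LinkageScan, families=None, ids=None
) -> list[FamilyLOD]:
    """Per-family LOD contributions at the peak locus.

    Both the H1 and H0 per-family log-likelihoods are evaluated at the global
    maximum-likelihood estimates, so the contributions sum exactly to the
    total LOD at the locus.
    """
    blocks = FamilyBlocks(y, X, kinship, families)
    if ids is None:
        if not isinstance(kinship, KinshipMatrix):
            raise ValueError("pass ids= when kinship is a bare matrix")
        ids = kinship.ids
    peak = next(
        (l for l in scan.loci if (l.chrom, l.pos) == (ibd_at_peak.chrom, ibd_at_peak.pos)),
        None,
    )
    if peak is None:
        raise ValueError("ibd_at_peak locus not present in scan")
    pis = blocks.gather(ibd_at_peak.reindex(ids))
    c1 = peak.components
    a1 = c1.sigma2_g / c1.sigma2_e
    b1 = c1.sigma2_q / c1.sigma2_e
    ll1_f = blocks.family_logliks(a1, b1, peak.beta, c1.sigma2_e, pis)
    null = scan.null_fit
    ll0_f = blocks.family_logliks(
        null.a, 0.0, null.beta, null.components.sigma2_e, None
    )
    return [
        FamilyLOD(
            family_id=str(f),
            pedlod=(ll1_f[f] - ll0_f[f]) / _LN10,
            n_members=blocks.family_sizes[f],
        )
        for f in blocks.family_ids
    ]


def select_linked_families(
    fams: list[FamilyLOD],
    pedlod_threshold: float = 0.1,
    pedlod_per_n_threshold: float = 0.01,
    cumulative_lod: float = 9.0,
) -> dict:
    """Linkage-enriched family selection.

    potentially_linked: families with pedlod > 0.1 or pedlod/N > 0.01 (N the
    number of phenotyped members).  top_linked: the smallest set of
    highest-LOD families whose cumulative pedlod reaches 9; empty, with a
    warning, when the total never gets there.
    """
    potentially = {
        f.family_id
        for f in fams
        if f.pedlod > pedlod_threshold
        or (f.n_members > 0 and f.pedlod / f.n_members > pedlod_per_n_threshold)
    }
    ranked = sorted(fams, key=lambda f: (-f.pedlod, f.family_id))
    top: set[str] = set()
    cum = 0.0
    reached = False
    for f in ranked:
        top.add(f.family_id)
        cum += f.pedlod
        if cum >= cumulative_lod:
            reached = True
            break
    if not reached:
        warnings.warn(
            f"cumulative pedigree LOD never reaches {cumulative_lod}; "
            "no top-linked set",
            stacklevel=2,
        )
        top = set()
    return {"potentially_linked": potentially, "top_linked": top}


def support_interval(scan: LinkageScan, drop: float = 1.0):
    """Closed support interval around the linkage peak.

    The maximal contiguous run of scanned loci on the peak chromosome,
    containing the peak, with LOD >= peak - drop.  When the peak itself does
    not exceed ``drop`` the whole scanned range is returned with a warning.
    Returns ((chrom, left_pos), (chrom, right_pos)).
    """
    if not scan.loci:
        raise ValueError("empty scan")
    loci = sorted(scan.loci, key=lambda l: (str(l.chrom), l.pos))
    peak = max(loci, key=lambda l: l.lod)
    if peak.lod <= drop:
        warnings.warn(
            "peak LOD does not exceed the drop; support interval is the full "
            "scanned range",
            stacklevel=2,
        )
        return ((loci[0].chrom, loci[0].pos), (loci[-1].chrom, loci[-1].pos))
    same = [l for l in loci if str(l.chrom) == str(peak.chrom)]
    k = same.index(peak)
    thr = peak.lod - drop
    left = k
    while left > 0 and same[left - 1].lod >= thr:
        left -= 1
    right = k
    while right < len(same) - 1 and same[right + 1].lod >= thr:
        right += 1
    if left == 0 and right == len(same) - 1 and len(same) > 1:
        warnings.warn(
            "support interval spans the full scanned range on the peak "
            "chromosome; the peak is not localised",
            stacklevel=2,
        )
    return ((peak.chrom, same[left].pos), (peak.chrom, same[right].pos))


def linkage_accounted(
    y, X, kinship, ibd_at_peak: IBDMatrix, g, families=None, ids=None
) -> dict:
    """Percent of the linkage signal accounted for by a variant.

    Refits the locus LOD with the variant dosage g appended to the fixed
    effects (in both H1 and H0); percent = 100 * (LOD0 - LODg) / LOD0.
    Negative values (the conditioned LOD exceeding the original) are reported
    as-is and flagged.  Requires LOD0 > 0.
    """
    scan0 = lod_scan(y, X, kinship, [ibd_at_peak], families=families, ids=ids)
    lod0 = scan0.peak_lod
    if lod0 <= 0:
        raise ValueError("LOD without the variant is 0; percent undefined")
    g = np.asarray(g, dtype=float)
    if np.any(np.isnan(g)):
        raise ValueError("missing dosages in the conditioning variant")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Xg = np.column_stack([X, g])
    scan_g = lod_scan(y, Xg, kinship, [ibd_at_peak], families=families, ids=ids)
    lodg = scan_g.peak_lod
    percent = 100.0 * (lod0 - lodg) / lod0
    flagged = percent < 0
    if flagged:
        logger.warning("conditioned LOD exceeds unconditioned; percent = %.2f", percent)
    return {"lod0": lod0, "lod_conditioned": lodg, "percent": percent, "negative": flagged}
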