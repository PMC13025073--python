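"""Evolutionary-parameter inference from bulk-sequencing read counts.

Inference runs in two stages.

**Stage 1 — clustering and class assignment.**  The observed VAF
distribution is decomposed into mutation clusters (binomial mixture, EM,
BIC model selection) and clusters are assigned to the five genealogical
classes (root / trunk / branch / successive / incidental) by maximizing a
cluster-level joint likelihood

    L = prod_clusters Poisson(cluster size | mu * generations spanned)
      * prod_mutations Binomial(alt reads | depth, purity * f_class / 2)

with class-expected fractions from :mod:`cloneclock.growth` and
closed-form parameter blocks (P from the branch-cluster MLE, mu and tf
from the Poisson counts, lambda_beta from the log-linear decay of trunk
centers, s from the successive ladder or a census closure).

**Stage 2 — structured point-process fit.**  On realized branching-process
data the one-cluster-per-generation decomposition is not identifiable at
routine depths (early trunk cohorts bottleneck to cell fraction 1; late
trunk, branch and early subclone cohorts all collapse to exactly P), so
the cluster-level fit only seeds a maximization of a thinned-Poisson
point-process likelihood over (alt, depth), whose intensity combines a
clonal atom, the trunk decay continuum, a free atom at P absorbing
collapsed generations, and mu-tied neutral 1/f^2 tails for both clones
(see :class:`_StructuredModel`).  The selection coefficient s and the
sampling time te are reported through the clone-ratio identity closed by
an assumed final tumor size, the only s-information a single timepoint
carries reliably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from sklearn.cluster import kmeans_plusplus

from .growth import (
    EvolutionParams,
    MutationClass,
    net_growth_rate,
    solve_sampling_time,
)

__all__ = [
    "InferenceConfig",
    "ClusterSet",
    "Estimates",
    "cluster_fractions",
    "assign_classes",
    "fit_parameters",
    "assess_analyzability",
]


@dataclass
class InferenceConfig:
    """Tunable knobs of the inference engine (all defaults are logged)."""

    purity: float = 1.0
    k_max: int = 12
    em_restarts: int = 10
    em_max_iter: int = 300
    em_tol: float = 1e-7
    #: restarts run this many burn-in iterations; only the best two continue
    em_short_iter: int = 25
    #: stop growing k once BIC has not improved for this many consecutive k
    em_patience: int = 3
    #: clusterings whose BIC is within this of the optimum are also offered
    #: to the class-assignment search (the joint likelihood arbitrates)
    bic_window: float = 60.0
    max_alternates: int = 4
    #: a cluster counts as clonal (root) if its center is within this of 1
    root_tolerance: float = 0.1
    #: analyzability bounds on the inferred subclone fraction
    p_lo: float = 0.02
    p_hi: float = 0.98
    #: fitted selection coefficients beyond this are treated as degenerate
    #: fits, not biology (the model regime is modest fitness advantages)
    s_max: float = 5.0
    #: identifiability floor: a fitted advantage below this cannot be told
    #: apart from neutral nested-lineage structure at a single timepoint
    s_min: float = 0.1
    #: initial / fallback ancestral net growth rate (death rate 0.2)
    lambda_beta0: float = net_growth_rate(0.2)
    #: final tumor size assumed by the census closure for s when no
    #: successive cluster is resolved
    assumed_population_size: float = 1e8
    bootstrap_n: int = 100
    min_mutations: int = 50
    max_successive: int = 8
    # -- structured point-process likelihood --
    #: cell-fraction grid for the intensity model (geometric spacing)
    grid_size: int = 140
    grid_f_lo: float = 3e-4
    #: minimum alt reads assumed by the detection model (match the gate)
    det_min_alt: int = 3
    #: mutations below this VAF are excluded from inference; the
    #: two-population structure lives in the high-frequency spectrum and
    #: the ultra-deep neutral tail carries no additional information about
    #: it (at 120x the minimum-read filter already implies this floor)
    vaf_floor: float = 0.02
    #: neutral-tail shape constants of the branching process, measured on
    #: the generator: N(>=u) = tail_norm * (mu c / (m u)) * exp(-(u/(b c))^k)
    tail_norm: float = 0.94
    tail_shape_ancestral: tuple[float, float] = (0.28, 1.15)
    tail_shape_subclone: tuple[float, float] = (0.75, 0.90)
    #: lognormal dispersion of realized tail amplitudes around their
    #: mu-tied expectations (lineage lumpiness, measured on the generator);
    #: the fit carries one free log-amplitude offset per tail, penalized by
    #: a Gaussian with these scales
    tail_sigma_ancestral: float = 0.2
    tail_sigma_subclone: float = 0.45
    #: subclone evidence: full model must beat the clonal-only null by this
    #: many log-likelihood units per extra parameter (BIC-style, times ln n)
    evidence_factor: float = 1.0
    lbfgs_maxiter: int = 60
    bootstrap_maxiter: int = 8
    #: weight (fraction of mutations) of a uniform background component,
    #: robustifying the fit against the lumpiness of realized lineage tails
    robust_background: float = 0.02
    #: reject optima whose clonal cluster sits more than this many standard
    #: errors below purity/2 (root mutations are carried by every cell)
    root_shift_z: float = 3.0
    #: expected number of early trunk generations bottlenecked into the
    #: clonal cluster (sole-surviving foundation lineage), measured on the
    #: branching process; added back to the fitted emergence time
    root_collapse_gens: float = 0.6
    #: likewise, early subclone generations bottlenecked at exactly P are
    #: absorbed by the branch atom; subtracted from its generation count
    branch_collapse_gens: float = 0.45


@dataclass
class ClusterSet:
    """VAF clusters with sufficient statistics and (optional) class map.

    ``centers`` are on the cell-fraction scale, sorted descending;
    ``assignment`` maps each input mutation to its cluster index.
    ``class_map`` maps cluster index to a mutation-class label once
    :func:`assign_classes` has run; ``failure_reason`` is set instead when
    no admissible assignment exists.
    """

    centers: np.ndarray
    sizes: np.ndarray
    alt_sums: np.ndarray
    depth_sums: np.ndarray
    logdp1_sums: np.ndarray
    assignment: np.ndarray
    k: int
    loglik: float
    bic: float
    purity: float
    class_map: dict[int, str] | None = None
    failure_reason: str | None = None
    #: near-optimal clusterings at other k, offered to the class search
    alternates: list["ClusterSet"] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "center": self.centers,
                "size": self.sizes,
            }
        )
        if self.class_map is not None:
            df["mutation_class"] = [self.class_map.get(j, "") for j in range(self.k)]
        return df


@dataclass
class Estimates:
    """Inferred parameters plus diagnostics for one sample."""

    params: EvolutionParams
    se: dict = field(default_factory=dict)
    loglik: float = -math.inf
    n_iterations: int = 0
    converged: bool = False
    analyzable: bool | None = None
    reasons: list[str] = field(default_factory=list)
    s_path: str | None = None
    cluster_summary: pd.DataFrame | None = None
    trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "mu": p.mu,
            "s": p.s,
            "tf": p.tf,
            "te": p.te,
            "lambda_beta": p.lambda_beta,
            "P": p.P,
            "se": self.se,
            "loglik": self.loglik,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "analyzable": self.analyzable,
            "reasons": self.reasons,
            "s_path": self.s_path,
        }


# ---------------------------------------------------------------------------
# Binomial mixture clustering
# ---------------------------------------------------------------------------

def _em_binomial(alt, depth, lnC, q0, w0, max_iter, tol):
    """EM for a k-component binomial mixture; returns (q, w, loglik)."""
    n = alt.size
    q = np.clip(np.asarray(q0, dtype=float), 1e-6, 1 - 1e-6)
    w = np.clip(np.asarray(w0, dtype=float), 1e-10, None)
    w = w / w.sum()
    a = alt[:, None]
    d = depth[:, None]
    ll_prev = -np.inf
    for _ in range(max_iter):
        logp = np.log(w)[None, :] + a * np.log(q)[None, :] + (d - a) * np.log1p(-q)[None, :]
        m = logsumexp(logp, axis=1)
        ll = float(m.sum() + lnC.sum())
        r = np.exp(logp - m[:, None])
        w = np.clip(r.mean(axis=0), 1e-10, None)
        w = w / w.sum()
        num = (r * alt[:, None]).sum(axis=0)
        den = (r * depth[:, None]).sum(axis=0)
        q = np.clip(num / np.maximum(den, 1e-300), 1e-6, 1 - 1e-6)
        if ll - ll_prev < tol * max(n, 1) and np.isfinite(ll_prev):
            ll_prev = ll
            break
        ll_prev = ll
    return q, w, ll_prev


def _harden(alt, depth, q, w, ll, bic, config) -> ClusterSet:
    """Hard-assign mutations to components; drop empty / merge duplicates."""
    logp = np.log(w)[None, :] + alt[:, None] * np.log(q)[None, :] + (
        depth[:, None] - alt[:, None]
    ) * np.log1p(-q)[None, :]
    assign = np.argmax(logp, axis=1)
    keep = np.unique(assign)
    q = q[keep]
    remap = {old: new for new, old in enumerate(keep)}
    assign = np.array([remap[a] for a in assign])
    order = np.argsort(-q)
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    assign = rank[assign]
    q = q[order]

    merged_q: list[float] = []
    merge_map = np.zeros(q.size, dtype=int)
    for j, qj in enumerate(q):
        if merged_q and abs(merged_q[-1] - qj) < 1e-4:
            merge_map[j] = len(merged_q) - 1
        else:
            merge_map[j] = len(merged_q)
            merged_q.append(float(qj))
    assign = merge_map[assign]
    kk = len(merged_q)

    sizes = np.bincount(assign, minlength=kk).astype(float)
    alt_sums = np.bincount(assign, weights=alt, minlength=kk)
    depth_sums = np.bincount(assign, weights=depth, minlength=kk)
    logdp1 = np.bincount(assign, weights=np.log(depth + 1.0), minlength=kk)
    centers = np.minimum(
        2.0 * alt_sums / np.maximum(depth_sums, 1e-300) / config.purity, 1.0
    )
    return ClusterSet(
        centers=centers, sizes=sizes, alt_sums=alt_sums, depth_sums=depth_sums,
        logdp1_sums=logdp1, assignment=assign, k=kk,
        loglik=ll, bic=bic, purity=config.purity,
    )


def cluster_fractions(
    calls: pd.DataFrame,
    k_max: int = 12,
    seed: int = 0,
    config: InferenceConfig | None = None,
) -> ClusterSet:
    """Fit binomial mixtures on (alt_reads, depth) and select k by BIC.

    For each k in 1..k_max the EM is run from ``em_restarts`` k-means++
    initializations on the VAFs (deterministic given ``seed``); restarts go
    through a short burn-in and the two most promising are run to
    convergence.  The clustering minimizing ``BIC = -2 logL + (2k - 1) ln n``
    is returned; near-optimal clusterings at other k (within ``bic_window``)
    are attached as ``alternates`` so that the class-assignment search —
    which knows the expected Poisson cluster sizes and the fraction decay
    the free mixture is blind to — can arbitrate among them.
    """
    config = config or InferenceConfig()
    alt = calls["alt_reads"].to_numpy(dtype=float)
    depth = calls["depth"].to_numpy(dtype=float)
    n = alt.size
    if n < 2:
        raise ValueError(f"need at least 2 mutations to cluster, got {n}")
    vaf = np.where(depth > 0, alt / depth, 0.0)
    lnC = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)

    by_k = []
    since_best = 0
    for k in range(1, min(k_max, n) + 1):
        if k == 1:
            q = np.array([np.clip(alt.sum() / max(depth.sum(), 1e-300), 1e-6, 1 - 1e-6)])
            w = np.array([1.0])
            ll = float(
                (lnC + alt * np.log(q[0]) + (depth - alt) * np.log1p(-q[0])).sum()
            )
            cand = (q, w, ll)
        else:
            shortlist = []
            for restart in range(config.em_restarts):
                rs = int(
                    np.random.default_rng([int(seed), k, restart]).integers(0, 2**31 - 1)
                )
                centers, _ = kmeans_plusplus(
                    vaf.reshape(-1, 1), n_clusters=k, random_state=rs
                )
                q0 = np.sort(centers.ravel())
                q, w, ll = _em_binomial(
                    alt, depth, lnC, q0, np.full(k, 1.0 / k),
                    config.em_short_iter, config.em_tol,
                )
                shortlist.append((ll, q, w))
            shortlist.sort(key=lambda t: -t[0])
            cand = None
            for ll0, q0, w0 in shortlist[:2]:
                q, w, ll = _em_binomial(
                    alt, depth, lnC, q0, w0, config.em_max_iter, config.em_tol
                )
                if cand is None or ll > cand[2]:
                    cand = (q, w, ll)
        q, w, ll = cand
        bic = -2.0 * ll + (2 * k - 1) * math.log(n)
        by_k.append((bic, k, q, w, ll))
        if bic <= min(b[0] for b in by_k) + 1e-9:
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.em_patience:
                break

    by_k.sort(key=lambda t: (t[0], t[1]))
    bic_best = by_k[0][0]
    main = _harden(alt, depth, by_k[0][2], by_k[0][3], by_k[0][4], by_k[0][0], config)
    for bic, k, q, w, ll in by_k[1 : 1 + config.max_alternates]:
        if bic <= bic_best + config.bic_window:
            main.alternates.append(_harden(alt, depth, q, w, ll, bic, config))
    return main


# ---------------------------------------------------------------------------
# Block-coordinate parameter fit for a fixed class map
# ---------------------------------------------------------------------------

@dataclass
class _BlockFit:
    mu: float
    s: float
    tf: float
    te: float
    lambda_beta: float
    P: float
    loglik: float
    s_path: str
    trunk_gens: list[float]
    trunk_mult: list[int]
    successive_deltas: list[int]
    n_root: float
    n_incidental: float


def _binom_term(alt_sum, depth_sum, frac, purity):
    p = min(max(purity * frac / 2.0, 1e-12), 1.0 - 1e-12)
    return alt_sum * math.log(p) + (depth_sum - alt_sum) * math.log1p(-p)


def _poisson_term(n, lam):
    lam = max(lam, 1e-12)
    return n * math.log(lam) - lam - float(gammaln(n + 1))


def _fit_blocks(clusters: ClusterSet, class_map: dict[int, str], config: InferenceConfig):
    """Closed-form block estimates and joint log-likelihood for one class map.

    Returns a :class:`_BlockFit` or None when the map is inadmissible
    (e.g. a trunk center at or below P, a successive center implying s <= 0).
    The log-likelihood omits per-mutation binomial normalization constants,
    which are identical across maps.
    """
    rho = config.purity
    idx_root = [j for j, c in class_map.items() if c == "root"]
    idx_trunk = sorted(
        (j for j, c in class_map.items() if c == "trunk"),
        key=lambda j: -clusters.centers[j],
    )
    idx_branch = [j for j, c in class_map.items() if c == "branch"]
    idx_succ = sorted(
        (j for j, c in class_map.items() if c == "successive"),
        key=lambda j: -clusters.centers[j],
    )
    idx_inc = [j for j, c in class_map.items() if c == "incidental"]
    if not idx_root or not idx_branch:
        return None
    b = idx_branch[0]
    P = float(
        min(2.0 * clusters.alt_sums[b] / max(clusters.depth_sums[b], 1e-300) / rho, 1.0)
    )
    if not 1e-6 < P < 1.0 - 1e-6:
        return None

    n_b = float(clusters.sizes[b])
    n_trunk = float(sum(clusters.sizes[j] for j in idx_trunk))
    T = len(idx_trunk)
    if T == 0 or n_b <= 0:
        return None

    # joint Poisson MLE for (mu, number of trunk generations)
    mu = max(n_b, 1.0)
    G = max(T, int(round(n_trunk / mu)))
    for _ in range(3):
        mu = (n_trunk + n_b) / (G + 1)
        G = max(T, int(round(n_trunk / max(mu, 1e-9))))
    mu = (n_trunk + n_b) / (G + 1)
    tf = n_trunk / max(mu, 1e-9) + 1.0

    # distribute the G trunk generations over the T trunk clusters
    mult = [max(1, int(round(clusters.sizes[j] / max(mu, 1e-9)))) for j in idx_trunk]
    while sum(mult) > G:
        j = int(np.argmax(mult))
        if mult[j] == 1:
            break
        mult[j] -= 1
    while sum(mult) < G:
        resid = [clusters.sizes[idx_trunk[i]] / max(mu, 1e-9) - mult[i] for i in range(T)]
        mult[int(np.argmax(resid))] += 1
    gens: list[float] = []
    gen_ranges: list[range] = []
    start = 1
    for m in mult:
        gen_ranges.append(range(start, start + m))
        gens.append(start + (m - 1) / 2.0)
        start += m

    # lambda_beta from the log-linear decay of trunk centers toward P
    xs, ws, gs = [], [], []
    for j, g in zip(idx_trunk, gens):
        c = float(clusters.centers[j])
        if c <= P + 1e-9 or c >= 1.0:
            return None
        xs.append(-math.log((c - P) / (1.0 - P)))
        ws.append(float(clusters.sizes[j]))
        gs.append(g)
    xs_a, ws_a, gs_a = np.array(xs), np.array(ws), np.array(gs)
    lam = float((ws_a * xs_a * gs_a).sum() / (ws_a * gs_a**2).sum())
    if not np.isfinite(lam) or lam <= 0:
        return None
    lam = float(np.clip(lam, 0.05, 1.5))

    # s from the successive ladder, or census closure without one
    deltas: list[int] = []
    if idx_succ:
        x1 = math.log(P / float(clusters.centers[idx_succ[0]]))
        one_plus_s = x1 / lam
        if one_plus_s <= 1.0:
            return None
        deltas = [1]
        for j in idx_succ[1:]:
            c = float(clusters.centers[j])
            if c <= 0 or c >= P:
                return None
            x = math.log(P / c)
            d = max(deltas[-1] + 1, int(round(x / (lam * one_plus_s))))
            deltas.append(d)
        xs_s = np.array([math.log(P / float(clusters.centers[j])) for j in idx_succ])
        ns_s = np.array([float(clusters.sizes[j]) for j in idx_succ])
        ds_s = np.array(deltas, dtype=float)
        one_plus_s = float((ns_s * xs_s * ds_s).sum() / (lam * (ns_s * ds_s**2).sum()))
        s = one_plus_s - 1.0
        if s <= 0:
            return None
        s_path = "successive"
    else:
        te0 = math.log(max(1.0 - P, 1e-12) * config.assumed_population_size) / lam
        if te0 <= tf:
            return None
        s = (math.log(P / (1.0 - P)) / lam + tf) / (te0 - tf)
        if s <= 0:
            return None
        s_path = "census"

    try:
        te = solve_sampling_time(P, s, tf, lam)
    except (ValueError, ZeroDivisionError):
        return None
    if not np.isfinite(te) or te <= tf:
        return None

    # joint log-likelihood (constants over maps omitted)
    ll = 0.0
    for j in idx_root:
        ll += _binom_term(clusters.alt_sums[j], clusters.depth_sums[j], 1.0, rho)
    for j, rng_g, m in zip(idx_trunk, gen_ranges, mult):
        fbar = P + (1.0 - P) * float(np.mean(np.exp(-lam * np.arange(rng_g.start, rng_g.stop))))
        ll += _binom_term(clusters.alt_sums[j], clusters.depth_sums[j], fbar, rho)
        ll += _poisson_term(clusters.sizes[j], mu * m)
    ll += _binom_term(clusters.alt_sums[b], clusters.depth_sums[b], P, rho)
    ll += _poisson_term(n_b, mu)
    for j, d in zip(idx_succ, deltas):
        fs = P * math.exp(-lam * (1.0 + s) * d)
        ll += _binom_term(clusters.alt_sums[j], clusters.depth_sums[j], fs, rho)
        ll += _poisson_term(clusters.sizes[j], mu)
    for j in idx_inc:
        ll -= float(clusters.logdp1_sums[j])

    return _BlockFit(
        mu=float(mu), s=float(s), tf=float(tf), te=float(te),
        lambda_beta=lam, P=P, loglik=float(ll), s_path=s_path,
        trunk_gens=gens, trunk_mult=mult, successive_deltas=deltas,
        n_root=float(sum(clusters.sizes[j] for j in idx_root)),
        n_incidental=float(sum(clusters.sizes[j] for j in idx_inc)),
    )


# ---------------------------------------------------------------------------
# Class assignment
# ---------------------------------------------------------------------------

def _candidate_maps(clusters: ClusterSet, config: InferenceConfig, branch_idx=None):
    """Enumerate admissible class maps (branch choice x successive depth)."""
    root = int(np.argmin(np.abs(clusters.centers - 1.0)))
    if abs(clusters.centers[root] - 1.0) > config.root_tolerance:
        return None, "no_root", []
    non_root = [j for j in range(clusters.k) if j != root]
    if not non_root:
        return root, "no_subclone", []
    branch_choices = non_root if branch_idx is None else [branch_idx]
    maps = []
    for b in branch_choices:
        if b == root:
            continue
        above = [j for j in non_root if clusters.centers[j] > clusters.centers[b]]
        below = sorted(
            (j for j in non_root if j != b and clusters.centers[j] < clusters.centers[b]),
            key=lambda j: -clusters.centers[j],
        )
        if not above:
            continue  # hard floor: root + >=1 trunk + branch
        for k_s in range(0, min(len(below), config.max_successive) + 1):
            cmap = {root: "root", b: "branch"}
            for j in above:
                cmap[j] = "trunk"
            for u, j in enumerate(below):
                cmap[j] = "successive" if u < k_s else "incidental"
            maps.append((b, cmap))
    if not maps:
        return root, "no_subclone", []
    return root, None, maps


def assign_classes(
    clusters: ClusterSet,
    p_hint: float | None = None,
    config: InferenceConfig | None = None,
) -> ClusterSet:
    """Assign clusters to mutation classes, maximizing the joint likelihood.

    The cluster nearest cell fraction 1 (within the root tolerance) is root;
    every admissible branch choice (with at least one trunk cluster above
    it) and successive-ladder depth is scored by the block-fit likelihood,
    ties going to the larger branch fraction (earlier emergence).  With a
    prior ``p_hint`` (from a previous iteration) the branch candidate is
    pinned to the nearest cluster.  On failure ``class_map`` stays None and
    ``failure_reason`` is set ("no_root" / "no_subclone").
    """
    config = config or InferenceConfig()
    best = None
    failures = []
    for cs in [clusters, *clusters.alternates]:
        branch_idx = None
        if p_hint is not None:
            root = int(np.argmin(np.abs(cs.centers - 1.0)))
            others = [j for j in range(cs.k) if j != root]
            if others:
                branch_idx = min(others, key=lambda j: abs(cs.centers[j] - p_hint))
        root, failure, maps = _candidate_maps(cs, config, branch_idx)
        if failure:
            failures.append(failure)
            continue
        for b, cmap in maps:
            fit = _fit_blocks(cs, cmap, config)
            if fit is None:
                continue
            key = (fit.loglik, cs.centers[b])
            if best is None or key > best[0]:
                best = (key, cmap, fit, cs)
        if best is None:
            failures.append("no_subclone")
    if best is None:
        out = ClusterSet(**{f: getattr(clusters, f) for f in (
            "centers", "sizes", "alt_sums", "depth_sums", "logdp1_sums",
            "assignment", "k", "loglik", "bic", "purity")})
        out.failure_reason = failures[0] if failures else "no_subclone"
        return out
    _, cmap, fit, cs = best
    out = ClusterSet(**{f: getattr(cs, f) for f in (
        "centers", "sizes", "alt_sums", "depth_sums", "logdp1_sums",
        "assignment", "k", "loglik", "bic", "purity")})
    out.class_map = cmap
    out.alternates = list(clusters.alternates)
    return out


# ---------------------------------------------------------------------------
# Structured point-process likelihood
# ---------------------------------------------------------------------------
#
# The realized branching process collapses much of the idealized cluster
# ladder: early trunk cohorts ride single-survivor bottlenecks to cell
# fraction 1, late trunk / branch / early subclone cohorts all sit at
# exactly P, and both clones shed polyphyletic 1/f^2 neutral tails.  Rather
# than forcing a one-cluster-per-generation decomposition, the final fit
# treats the mutation set as a thinned Poisson point process over
# (alt, depth) whose intensity is built from the growth model:
#
# * a clonal atom at fraction 1 with free weight (root mutations plus
#   bottlenecked trunk cohorts);
# * trunk intensity: mass mu per generation mapped through the decay
#   x = ln((1-P)/(f-P)) = lambda_beta * t, i.e. density mu/lambda_beta per
#   unit x on t in (0.5, tf - 0.5);
# * a branch atom of mass mu at exactly P;
# * subclone and ancestral neutral tails with amplitudes tied to mu:
#   N(>=u) = 0.94 * mu c / (m u) * exp(-(u/(b c))^k), where (c, m) is
#   (P, lambda_beta (1+s)) or (1-P, lambda_beta) and (b, k) are shape
#   constants measured on the branching process itself;
# * detection thinning for the minimum-alt-read filter.
#
# mu is then identified by the trunk slope and the tail amplitudes, tf by
# the total foundation-lineage mass (including everything collapsed at P),
# and s by the subclone-tail amplitude; none of these require resolving
# clusters that the process itself does not separate.

from scipy.optimize import minimize
from scipy.special import betainc, gammainc


def effective_min_alt(config: InferenceConfig, mean_depth: float) -> int:
    """Minimum alt-read count implied by the VAF resolution floor.

    Equals the plain minimum-support threshold at routine depths (~120x)
    and rises with depth so that inference never descends below the VAF
    floor; used identically for filtering and for the detection model.
    """
    return int(max(config.det_min_alt, math.ceil(config.vaf_floor * mean_depth)))


class _StructuredModel:
    """Precomputed kernels + intensity evaluation for one sample."""

    def __init__(self, alt, depth, config: InferenceConfig):
        self.config = config
        self.lam = config.lambda_beta0
        self.n = alt.size
        rho = config.purity
        G = config.grid_size
        self.f_edges = np.geomspace(config.grid_f_lo, 1.0, G + 1)
        self.f_centers = np.sqrt(self.f_edges[:-1] * self.f_edges[1:])
        p_edges = np.clip(rho * self.f_edges / 2.0, 1e-12, 1 - 1e-12)

        a = alt[:, None]
        d = depth[:, None]
        ib = betainc(a + 1.0, d - a + 1.0, p_edges[None, :])
        # average binomial pmf over each grid cell (exact cell integral)
        self.B = (ib[:, 1:] - ib[:, :-1]) / ((d + 1.0) * np.diff(p_edges)[None, :])
        self.B = np.maximum(self.B, 0.0)
        self.alt = alt
        self.depth = depth
        self._lnC = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
        p1 = min(rho / 2.0, 1 - 1e-12)
        self.B_root = np.exp(self._lnC + alt * math.log(p1) + (depth - alt) * math.log1p(-p1))

        d_nom = max(float(depth.mean()), 1.0)
        # depth ~ Poisson and binomial thinning compose to alt ~ Poisson;
        # P(alt >= k) for alt ~ Poisson(m) is the regularized gammainc(k, m)
        k_det = effective_min_alt(config, d_nom)
        self.det = gammainc(k_det, d_nom * rho * self.f_centers / 2.0)
        self.det_at = lambda f: float(gammainc(k_det, d_nom * rho * f / 2.0))

    def _atom_kernel(self, f: float):
        rho = self.config.purity
        p = min(max(rho * f / 2.0, 1e-12), 1 - 1e-12)
        return np.exp(
            self._lnC + self.alt * math.log(p) + (self.depth - self.alt) * math.log1p(-p)
        )

    def _tail_masses(self, mu, c, m, shape):
        """Per-cell masses of a neutral 1/f^2 tail with clone size c, rate m."""
        b, k = shape
        u = np.minimum(self.f_edges, c)
        with np.errstate(divide="ignore"):
            N = self.config.tail_norm * mu * c / (m * u) * np.exp(-((u / (b * c)) ** k))
        return np.maximum(N[:-1] - N[1:], 0.0)

    def _trunk_masses(self, mu, P, tf):
        """Per-cell trunk masses: uniform mu/lambda in x on (0.5, tf-0.5) gens."""
        lam = self.lam
        lo, hi = 0.5 * lam, max(tf - 0.5, 0.5) * lam
        f = self.f_edges
        x = np.full_like(f, np.inf)
        above = f > P
        x[above] = np.log((1.0 - P) / np.maximum(f[above] - P, 1e-300))
        x = np.clip(x, lo, hi)  # x decreasing in f
        return np.maximum(x[:-1] - x[1:], 0.0) * (mu / lam)

    def masses(self, P, mu, tf, s, a_anc=0.0, a_sub=0.0):
        m_f = self.lam * (1.0 + s)
        cell = self._trunk_masses(mu, P, tf)
        cell += math.exp(a_sub) * self._tail_masses(
            mu, P, m_f, self.config.tail_shape_subclone
        )
        cell += math.exp(a_anc) * self._tail_masses(
            mu, 1.0 - P, self.lam, self.config.tail_shape_ancestral
        )
        return cell

    def loglik(self, z) -> float:
        P, mu, tf, s, wr, wb, a_anc, a_sub = _unpack(z)
        cell = self.masses(P, mu, tf, s, a_anc, a_sub)
        bg = self.config.robust_background * self.n
        ell = (self.B @ cell + wb * self._atom_kernel(P) + wr * self.B_root
               + bg / (self.depth + 1.0))
        Lam = float(cell @ self.det) + wb * self.det_at(P) + wr * self.det_at(1.0) + bg
        penalty = (
            a_anc**2 / (2 * self.config.tail_sigma_ancestral**2)
            + a_sub**2 / (2 * self.config.tail_sigma_subclone**2)
        )
        return float(np.log(np.maximum(ell, 1e-300)).sum() - Lam - penalty)

    def root_position_z(self, z) -> float:
        '''z-statistic of the root-assigned mutations' mean VAF against
        purity/2.  Root mutations are carried by every tumor cell, so a
        clonal cluster sitting significantly below purity/2 means the fit
        has absorbed genuinely subclonal mass into the clonal atom (the
        signature of a self-similar misinterpretation).'''
        P, mu, tf, s, wr, wb, a_anc, a_sub = _unpack(z)
        cell = self.masses(P, mu, tf, s, a_anc, a_sub)
        bg = self.config.robust_background * self.n
        other = self.B @ cell + wb * self._atom_kernel(P) + bg / (self.depth + 1.0)
        root_term = wr * self.B_root
        is_root = root_term > other
        n_root = int(is_root.sum())
        if n_root < 5:
            return 0.0
        vaf = self.alt[is_root] / self.depth[is_root]
        p0 = self.config.purity / 2.0
        se = math.sqrt(max(p0 * (1 - p0) / float(self.depth[is_root].sum()), 1e-12))
        return float((vaf.mean() - p0) / se)

    def loglik_null(self, z, lump_f: float | None = None) -> float:
        """Clonal-only null: root atom, neutral tail, one neutral lineage lump.

        The tail support is pinned at the physical top of a clonal tumor's
        neutral tail (the first-generation sibling lineage, about
        exp(-lambda_beta/2) of the tumor); a free support would let the
        null mimic genuine subclone structure.  A single free-weight atom
        at ``lump_f`` (the dominant sub-clonal cluster) represents the
        largest realized neutral lineage — one big lineage alone is not
        evidence of a fitter subclone.
        """
        wr, A, wl = math.exp(z[0]), math.exp(z[1]), math.exp(z[2])
        c = math.exp(-self.lam / 2.0)
        b, k = self.config.tail_shape_ancestral
        u = np.minimum(self.f_edges, c)
        with np.errstate(divide="ignore"):
            N = A / u * np.exp(-((u / (b * c)) ** k))
        cell = np.maximum(N[:-1] - N[1:], 0.0)
        bg = self.config.robust_background * self.n
        ell = self.B @ cell + wr * self.B_root + bg / (self.depth + 1.0)
        Lam = float(cell @ self.det) + wr * self.det_at(1.0) + bg
        if lump_f is not None:
            ell = ell + wl * self._atom_kernel(lump_f)
            Lam += wl * self.det_at(lump_f)
        return float(np.log(np.maximum(ell, 1e-300)).sum() - Lam)


# ---------------------------------------------------------------------------
# Full fit
# ---------------------------------------------------------------------------

def _failed_estimates(reason: str, clusters: ClusterSet | None = None) -> Estimates:
    return Estimates(
        params=EvolutionParams(),
        analyzable=False,
        reasons=[reason],
        cluster_summary=clusters.summary() if clusters is not None else None,
    )


#: optimizer box in transformed coordinates
#: (logit P, ln mu, ln(tf - 1), ln s, ln root-weight)
_Z_BOUNDS = [
    (-9.0, 9.0),
    (math.log(0.2), math.log(500.0)),
    (math.log(0.05), math.log(99.0)),
    (math.log(0.02), math.log(10.0)),
    (0.0, math.log(1e5)),
    (math.log(0.1), math.log(1e5)),
    (-2.0, 2.0),
    (-2.0, 2.0),
]
_ZN_BOUNDS = [
    (0.0, math.log(1e5)),
    (math.log(1e-3), math.log(1e5)),
    (math.log(1e-3), math.log(1e5)),
]


def _pack(P, mu, tf, s, wr, wb=None):
    P = min(max(P, 1e-4), 1 - 1e-4)
    z = np.array([
        math.log(P / (1 - P)),
        math.log(max(mu, 0.2)),
        math.log(max(tf - 1.0, 0.05)),
        math.log(min(max(s, 0.02), 10.0)),
        math.log(max(wr, 1.0)),
        math.log(max(wb if wb is not None else mu, 0.1)),
        0.0,
        0.0,
    ])
    return np.clip(z, [b[0] for b in _Z_BOUNDS], [b[1] for b in _Z_BOUNDS])


def _unpack(z):
    '''(P, mu, tf_cont, s, w_root, w_branch, a_anc, a_sub) from optimizer
    coordinates; the last two are log offsets of the tail amplitudes.'''
    P = 1.0 / (1.0 + math.exp(-z[0]))
    return (P, math.exp(z[1]), 1.0 + math.exp(z[2]), math.exp(z[3]),
            math.exp(z[4]), math.exp(z[5]), z[6], z[7])


def _census_closure(P, tf, lam, assumed_n):
    '''s and te from the clone-ratio identity closed by the assumed final size.

    te is the generation at which a tumor of final size assumed_n was
    sampled (its ancestral compartment alone has grown to (1-P) * N), and s
    then follows from ln(P/(1-P)) = lambda_beta (s te - (1+s) tf).
    '''
    if not 0.0 < P < 1.0 or tf <= 0:
        return math.nan, math.nan
    te = math.log(max(1.0 - P, 1e-12) * assumed_n) / lam
    if te <= tf:
        return math.nan, math.nan
    s = (math.log(P / (1.0 - P)) / lam + tf) / (te - tf)
    if s <= 0:
        return math.nan, math.nan
    return s, te


def _total_tf(mu, tf_cont, wb, branch_collapse=0.45):
    '''Emergence time including trunk generations collapsed at fraction P.

    Whole trunk generations whose ancestral-side descendants died out sit at
    exactly P and are absorbed by the branch-atom weight wb; its excess over
    the single branch generation (mass mu) converts back to generations.
    With no collapse wb fits about mu and the correction vanishes.
    '''
    return tf_cont + max(0.0, wb / max(mu, 1e-9) - 1.0 - branch_collapse)


def _candidate_starts(clusters: ClusterSet, model: _StructuredModel, fracs, config):
    """Starting points for the structured fit: the cluster-level block fit
    plus moment-initialized starts at each plausible branch-center P."""
    starts = []
    if clusters.class_map is not None:
        bf = _fit_blocks(clusters, clusters.class_map, config)
        if bf is not None:
            starts.append(_pack(bf.P, bf.mu, bf.tf, bf.s, max(bf.n_root, 1.0), bf.mu))
    cand = []
    for cs in [clusters, *clusters.alternates]:
        for c in cs.centers:
            c = float(c)
            if 0.02 <= c <= 0.96 and all(abs(c - c2) > 0.05 for c2 in cand):
                cand.append(c)
    cand = cand[:4]
    # a nearly fixed subclone hides next to the clonal cluster: always try
    for P0 in (0.90, 0.95):
        if all(abs(P0 - c2) > 0.04 for c2 in cand):
            cand.append(P0)
    wr0 = max(float((fracs > 0.93).sum()), 1.0)
    for P0 in cand:
        # moment init: mu from the detected low tail, tf from the mass above P
        tail = (fracs > 0.03) & (fracs < 0.6 * P0 + 0.02)
        unit = model.masses(P0, 1.0, 2.0, 0.5)
        sel = model.f_centers < 0.6 * P0 + 0.02
        pred1 = float((unit * model.det)[sel].sum())
        mu0 = min(max(float(tail.sum()) / max(pred1, 0.2), 1.0), 300.0)
        n_above = float(((fracs > P0 + 0.05) & (fracs < 0.93)).sum())
        tf0 = min(max(1.0 + n_above / mu0 + 1.0, 1.3), 60.0)
        wb0 = max(float((np.abs(fracs - P0) < 0.05).sum()), mu0)
        starts.append(_pack(P0, mu0, tf0, 0.5, wr0, wb0))
    return starts


def fit_parameters(
    clusters: ClusterSet,
    calls: pd.DataFrame,
    config: InferenceConfig | None = None,
    seed: int = 0,
) -> Estimates:
    """Maximize the structured joint likelihood for one sample.

    The cluster-level class map seeds the fit; the structured point-process
    likelihood (see :class:`_StructuredModel`) is then maximized from that
    seed and from moment-initialized starts at each plausible subclone
    fraction, keeping the best optimum (the recorded likelihood trace is
    non-decreasing by construction).  A clonal-only null model provides the
    subclone evidence test; standard errors come from a nonparametric
    bootstrap over mutations.
    """
    config = config or InferenceConfig()
    if clusters.failure_reason == "no_root":
        return _failed_estimates("no_root", clusters)
    alt = calls["alt_reads"].to_numpy(dtype=float)
    depth = calls["depth"].to_numpy(dtype=float)
    fracs = np.minimum(
        2.0 * np.where(depth > 0, alt / depth, 0.0) / config.purity, 1.0
    )
    model = _StructuredModel(alt, depth, config)
    n = alt.size

    best = None  # (ll, z, success, trace)
    for z0 in _candidate_starts(clusters, model, fracs, config):
        ll0 = model.loglik(z0)
        res = minimize(
            lambda z: -model.loglik(z), z0, method="L-BFGS-B",
            bounds=_Z_BOUNDS, options={"maxiter": config.lbfgs_maxiter},
        )
        if not res.success:  # polish once from where the budget ran out
            res = minimize(
                lambda z: -model.loglik(z), res.x, method="L-BFGS-B",
                bounds=_Z_BOUNDS, options={"maxiter": config.lbfgs_maxiter},
            )
        if -res.fun >= ll0:
            ok = bool(res.success) or float(np.max(np.abs(res.jac))) < 0.05 * math.sqrt(model.n)
            cand = (float(-res.fun), res.x, ok, [ll0, float(-res.fun)])
        else:  # optimizer failed to improve; keep the start
            cand = (ll0, z0, True, [ll0])
        if model.root_position_z(cand[1]) < -config.root_shift_z:
            continue  # clonal atom has swallowed subclonal mass
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None:
        return _failed_estimates(clusters.failure_reason or "no_subclone", clusters)
    ll_full, z_hat, success, trace = best
    assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:])), "likelihood must ascend"

    # subclone evidence against the clonal-only null (2 fewer parameters)
    wr0 = max(float((fracs > 0.93).sum()), 1.0)
    tail_n = max(float((fracs < 0.5).sum()), 1.0)
    ll_null = -np.inf
    lump_candidates: list[float | None] = [None]
    sub = [float(c) for c in clusters.centers if 0.05 <= c <= 0.9]
    if sub:
        sizes = {float(c): float(s) for c, s in zip(clusters.centers, clusters.sizes)}
        lump_candidates.append(max(sub, key=lambda c: sizes.get(c, 0.0)))
    for lump_f in lump_candidates:
        for a0 in (0.3, 3.0, 30.0):
            z0n = np.array([math.log(wr0), math.log(tail_n * a0 * 0.01 + 0.1), 2.0])
            z0n = np.clip(z0n, [b[0] for b in _ZN_BOUNDS], [b[1] for b in _ZN_BOUNDS])
            resn = minimize(
                lambda z: -model.loglik_null(z, lump_f), z0n, method="L-BFGS-B",
                bounds=_ZN_BOUNDS, options={"maxiter": config.lbfgs_maxiter},
            )
            ll_null = max(ll_null, float(-resn.fun), model.loglik_null(z0n, lump_f))
    threshold = config.evidence_factor * 1.5 * math.log(max(n, 2))
    if ll_full - ll_null < threshold:
        est = _failed_estimates("no_subclone", clusters)
        est.loglik = ll_full
        return est

    P, mu, tf_cont, s_tail, wr, wb, _, _ = _unpack(z_hat)
    tf = _total_tf(mu, tf_cont, wb, config.branch_collapse_gens) + config.root_collapse_gens
    # the tail-amplitude s is weakly identified from a single timepoint;
    # report s (and te) through the census closure instead
    s, te = _census_closure(P, tf, model.lam, config.assumed_population_size)
    se = _bootstrap_se(model, z_hat, config, seed)
    params_kwargs = dict(mu=mu, P=P, tf=tf, lambda_beta=model.lam)
    if np.isfinite(s):
        params_kwargs["s"] = s
    if np.isfinite(te) and te > tf:
        params_kwargs["te"] = te
    est = Estimates(
        params=EvolutionParams(**params_kwargs),
        se=se,
        loglik=ll_full,
        n_iterations=len(trace),
        converged=success,
        s_path="census",
        cluster_summary=clusters.summary(),
        trace=trace,
    )
    if tf - 1.0 < 1.0:
        est.reasons.append("no_trunk")
    est.analyzable, est.reasons = assess_analyzability(est, config)
    return est


def _bootstrap_se(model: _StructuredModel, z_hat, config: InferenceConfig, seed: int):
    """Nonparametric bootstrap over mutations, warm-started at the MLE."""
    rng = np.random.default_rng([int(seed), 0xB007])
    n = model.n
    boot = _StructuredModel.__new__(_StructuredModel)
    boot.__dict__.update(model.__dict__)
    draws: dict[str, list[float]] = {k: [] for k in ("mu", "s", "tf", "te", "P")}
    for _ in range(config.bootstrap_n):
        idx = rng.integers(0, n, size=n)
        boot.B = model.B[idx]
        boot.B_root = model.B_root[idx]
        boot.alt = model.alt[idx]
        boot.depth = model.depth[idx]
        boot._lnC = model._lnC[idx]
        res = minimize(
            lambda z: -boot.loglik(z), z_hat, method="L-BFGS-B",
            bounds=_Z_BOUNDS, options={"maxiter": config.bootstrap_maxiter},
        )
        P, mu, tf_cont, _, _, wb, _, _ = _unpack(res.x)
        tf = _total_tf(mu, tf_cont, wb, config.branch_collapse_gens) + config.root_collapse_gens
        s, te = _census_closure(P, tf, model.lam, config.assumed_population_size)
        for key, val in (("mu", mu), ("s", s), ("tf", tf), ("te", te), ("P", P)):
            draws[key].append(val)
    return {
        k: (float(np.nanstd(v, ddof=1)) if len(v) > 1 else math.nan)
        for k, v in draws.items()
    }


def assess_analyzability(
    estimates: Estimates, config: InferenceConfig | None = None
) -> tuple[bool, list[str]]:
    """Verdict on whether the complete parameter set was recovered.

    Analyzable iff all of (mu, s, tf, te, P) are finite and within their
    domains, the refinement converged, and the subclone fraction is not
    extreme (outside ``[p_lo, p_hi]``).  Reason codes accumulate rather
    than short-circuit.
    """
    config = config or InferenceConfig()
    p = estimates.params
    reasons = list(r for r in estimates.reasons if r not in (
        "extreme_subclone_fraction", "incomplete_parameters", "no_convergence"))
    if not p.is_complete:
        reasons.append("incomplete_parameters")
    else:
        if not (p.mu > 0 and p.s > 0 and p.tf > 0 and p.te > p.tf and 0 < p.P < 1):
            reasons.append("incomplete_parameters")
        elif not config.p_lo <= p.P <= config.p_hi:
            reasons.append("extreme_subclone_fraction")
        elif p.s > config.s_max:
            reasons.append("implausible_fitness")
        elif p.s < config.s_min:
            reasons.append("near_neutral_fit")
    if not estimates.converged:
        reasons.append("no_convergence")
    return (not reasons), reasons
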