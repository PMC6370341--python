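"""Codon-substitution models and tests of adaptive evolution.

The engine is the Goldman-Yang codon model on the 61 sense codons of the
universal genetic code: substitution rate from codon i to codon j is zero
unless they differ at one nucleotide, and otherwise proportional to the
target codon frequency pi_j, times kappa for a transition, times omega
(dN/dS) for a nonsynonymous change.  Site-class mixtures give the standard
site models:

* M0    — one omega for all sites
* M1a   — nearly-neutral: omega0 in (0,1) plus a neutral class (omega = 1)
* M2a   — M1a plus a positive-selection class (omega2 >= 1)
* M7    — omega ~ Beta(p, q) discretized into K equal-probability classes
* M8    — M7 plus a positive-selection class

and branch-site model A allows the positive-selection class only on
designated foreground branches (H0 fixes its omega to 1, H1 estimates it).
Branch lengths are taken as given and held fixed; a single global rate
multiplier is estimated to absorb the nucleotide-vs-codon unit difference.

A Nei-Gojobori (1986) counting estimator with Jukes-Cantor correction is
included as an independent sanity check on the likelihood machinery.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.optimize import minimize
from scipy.special import betainc, logsumexp
from scipy.stats import beta as beta_dist

from .io import Alignment

__all__ = [
    "CODONS",
    "CodonModel",
    "SiteClassModel",
    "BranchSiteModel",
    "f3x4_frequencies",
    "gy94_generator",
    "transition_matrix",
    "codon_loglik",
    "fit_site_models",
    "fit_branch_site",
    "nei_gojobori_dnds",
    "discrete_beta",
    "SiteModelFit",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
_AA = {c: _TABLE.forward_table[c] for c in CODONS}
_NUC = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _classify_pairs():
    """For each ordered codon pair differing at one site: (is_ti, is_syn)."""
    pairs = {}
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            pairs[(i, j)] = (
                (ci[k], cj[k]) in _TRANSITIONS,
                _AA[ci] == _AA[cj],
            )
    return pairs

_SINGLE_STEP = _classify_pairs()


@dataclass
class CodonModel:
    """Single-omega GY94 model."""

    kappa: float
    omega: float
    pi: np.ndarray = field(default_factory=lambda: np.full(61, 1 / 61))

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (61,) or abs(self.pi.sum() - 1) > 1e-9:
            raise ValueError("pi must be 61 frequencies summing to 1")


@dataclass
class SiteClassModel:
    """Mixture of GY94 classes sharing kappa and pi."""

    kappa: float
    classes: list[tuple[float, float]]  # (proportion, omega)
    pi: np.ndarray = field(default_factory=lambda: np.full(61, 1 / 61))

    def __post_init__(self) -> None:
        props = sum(p for p, _ in self.classes)
        if abs(props - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {props}, expected 1")
        if any(p < 0 or w < 0 for p, w in self.classes):
            raise ValueError("proportions and omegas must be >= 0")
        self.pi = np.asarray(self.pi, dtype=float)


@dataclass
class BranchSiteModel:
    """Branch-site model A with site classes 0, 1, 2a, 2b.

    ``p0`` and ``p1`` are the weights of the purifying (omega0) and neutral
    classes; the remainder splits proportionally into classes 2a/2b whose
    foreground omega is ``omega2`` (fixed to 1 under H0).  ``foreground`` is
    a set of frozensets of leaf labels; a branch is foreground when its
    descendant leaf set equals one of them.
    """

    kappa: float
    p0: float
    p1: float
    omega0: float
    omega2: float
    foreground: set
    pi: np.ndarray = field(default_factory=lambda: np.full(61, 1 / 61))

    def __post_init__(self) -> None:
        if not (self.p0 >= 0 and self.p1 >= 0 and self.p0 + self.p1 <= 1 + 1e-12):
            raise ValueError("p0, p1 must be >= 0 with p0 + p1 <= 1")
        if not (0 <= self.omega0 <= 1):
            raise ValueError("omega0 must be in [0, 1]")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")
        self.pi = np.asarray(self.pi, dtype=float)

    def class_table(self) -> list[tuple[str, float, float, float]]:
        """(name, proportion, background omega, foreground omega) per class."""
        p2 = max(0.0, 1.0 - self.p0 - self.p1)
        denom = self.p0 + self.p1
        if denom <= 0:
            share0, share1 = 0.5, 0.5
        else:
            share0, share1 = self.p0 / denom, self.p1 / denom
        return [
            ("0", self.p0, self.omega0, self.omega0),
            ("1", self.p1, 1.0, 1.0),
            ("2a", p2 * share0, self.omega0, self.omega2),
            ("2b", p2 * share1, 1.0, self.omega2),
        ]


def f3x4_frequencies(aln: Alignment) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide composition.

    Counts nucleotides separately at the three codon positions (gap and
    ambiguous characters skipped), multiplies per codon, and renormalizes
    over the 61 sense codons.  An in-frame stop codon in any sequence is an
    error.
    """
    if aln.length % 3 != 0:
        raise ValueError(f"alignment length {aln.length} not divisible by 3")
    counts = np.zeros((3, 4))
    for sid, seq in zip(aln.ids, aln.seqs):
        for site in range(0, aln.length, 3):
            codon = seq[site : site + 3]
            if codon in STOP_CODONS:
                raise ValueError(
                    f"in-frame stop codon {codon} in sequence {sid!r} "
                    f"at alignment position {site + 1}"
                )
            for pos, char in enumerate(codon):
                k = _NUC.find(char)
                if k >= 0:
                    counts[pos, k] += 1
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("no unambiguous nucleotides at some codon position")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.maximum(freqs, 1e-6)  # keep pi strictly positive
    freqs /= freqs.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, _NUC.index(c[0])]
            * freqs[1, _NUC.index(c[1])]
            * freqs[2, _NUC.index(c[2])]
            for c in CODONS
        ]
    )
    return pi / pi.sum()


def gy94_generator(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 rate matrix Q (61 x 61), scaled to one expected event per unit time.

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for single-
    nucleotide changes, 0 otherwise; rows sum to zero; reversible with
    respect to pi by construction.
    """
    pi = np.asarray(pi, dtype=float)
    Q = np.zeros((61, 61))
    for (i, j), (is_ti, is_syn) in _SINGLE_STEP.items():
        rate = pi[j]
        if is_ti:
            rate *= kappa
        if not is_syn:
            rate *= omega
        Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    if mu > 0:
        Q /= mu
    return Q


class _ReversibleExp:
    """Eigendecomposition of a reversible Q for fast P(t) over many branches."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self.w = w
        self.left = V / sqrt_pi[:, None]
        self.right = (V * sqrt_pi[:, None]).T

    def expm(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.w * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a reversible generator."""
    return _ReversibleExp(Q, pi).expm(t)


def _leaf_partial(codon: str) -> np.ndarray:
    """Indicator over sense codons compatible with a possibly gappy codon."""
    if codon in _CODON_INDEX:
        v = np.zeros(61)
        v[_CODON_INDEX[codon]] = 1.0
        return v
    if codon in STOP_CODONS:
        raise ValueError(f"in-frame stop codon {codon}")
    v = np.ones(61)
    for pos, char in enumerate(codon):
        if char in _NUC:
            mask = np.array([c[pos] == char for c in CODONS], dtype=float)
            v *= mask
    if v.sum() == 0:  # e.g. determined positions spell only stop codons
        raise ValueError(f"codon {codon!r} compatible with no sense codon")
    return v


def _codon_patterns(tree: dendropy.Tree, aln: Alignment):
    """Compress codon columns into unique patterns with multiplicities."""
    if aln.length % 3 != 0:
        raise ValueError(f"alignment length {aln.length} not divisible by 3")
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in aln.ids]
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {sorted(missing)}")
    seqs = {l: aln.sequence(l) for l in leaves}
    pattern_weight: dict[tuple, float] = {}
    for site in range(0, aln.length, 3):
        key = tuple(seqs[l][site : site + 3] for l in leaves)
        pattern_weight[key] = pattern_weight.get(key, 0.0) + 1.0
    patterns = list(pattern_weight)
    weights = np.array([pattern_weight[p] for p in patterns])
    partials = {}
    for li, leaf in enumerate(leaves):
        arr = np.empty((len(patterns), 61))
        cache: dict[str, np.ndarray] = {}
        for pi_, pat in enumerate(patterns):
            codon = pat[li]
            if codon not in cache:
                cache[codon] = _leaf_partial(codon)
            arr[pi_] = cache[codon]
        partials[leaf] = arr
    return leaves, partials, weights


def _class_site_logliks(tree, partials, pi, expms, scale, foreground_leafsets=None,
                        fg_expm=None):
    """Per-pattern log-likelihood for one rate class via scaled pruning."""
    npat = next(iter(partials.values())).shape[0]
    logscale = np.zeros(npat)
    stack: dict = {}
    leafsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            stack[node] = partials[node.taxon.label]
            leafsets[node] = frozenset([node.taxon.label])
        else:
            prod = None
            leafset = frozenset()
            for child in node.child_nodes():
                leafset |= leafsets[child]
            leafsets[node] = leafset
            for child in node.child_nodes():
                t = (child.edge.length or 0.0) * scale
                if (
                    foreground_leafsets is not None
                    and leafsets[child] in foreground_leafsets
                ):
                    P = fg_expm.expm(t)
                else:
                    P = expms.expm(t)
                contrib = stack[child] @ P.T
                prod = contrib if prod is None else prod * contrib
            mx = prod.max(axis=1)
            bad = mx <= 0
            if bad.any():
                raise ValueError("numerical underflow produced zero partials")
            prod /= mx[:, None]
            logscale += np.log(mx)
            stack[node] = prod
    root_like = stack[tree.seed_node] @ pi
    return np.log(root_like) + logscale


def codon_loglik(
    tree: dendropy.Tree,
    aln: Alignment,
    model,
    scale: float = 1.0,
) -> float:
    """Log-likelihood of a codon alignment under a GY94-family model.

    ``model`` may be a :class:`CodonModel`, :class:`SiteClassModel`, or
    :class:`BranchSiteModel`.  Branch lengths are multiplied by ``scale``
    (the global rate multiplier) and otherwise held fixed.  All-gap codon
    columns contribute zero information and leave the result unchanged.
    """
    leaves, partials, weights = _codon_patterns(tree, aln)
    pi = np.asarray(model.pi, dtype=float)

    if isinstance(model, CodonModel):
        classes = [(1.0, model.omega)]
        kappa = model.kappa
    elif isinstance(model, SiteClassModel):
        classes = list(model.classes)
        kappa = model.kappa
    elif isinstance(model, BranchSiteModel):
        return _branch_site_loglik(tree, partials, weights, model, scale)
    else:
        raise TypeError(f"unsupported model type {type(model)!r}")

    per_class = []
    log_props = []
    expm_cache: dict[float, _ReversibleExp] = {}
    for prop, omega in classes:
        if prop <= 0:
            continue
        if omega not in expm_cache:
            expm_cache[omega] = _ReversibleExp(gy94_generator(kappa, omega, pi), pi)
        site_ll = _class_site_logliks(tree, partials, pi, expm_cache[omega], scale)
        per_class.append(site_ll)
        log_props.append(math.log(prop))
    stacked = np.stack(per_class) + np.array(log_props)[:, None]
    site_logl = logsumexp(stacked, axis=0)
    result = float(np.dot(weights, site_logl))
    if math.isnan(result):
        raise FloatingPointError("NaN log-likelihood")
    return result


def _branch_site_loglik(tree, partials, weights, model: BranchSiteModel, scale):
    pi = model.pi
    fg = {frozenset(s) for s in model.foreground}
    per_class = []
    log_props = []
    cache: dict[float, _ReversibleExp] = {}

    def get(omega):
        if omega not in cache:
            cache[omega] = _ReversibleExp(gy94_generator(model.kappa, omega, pi), pi)
        return cache[omega]

    for _name, prop, w_bg, w_fg in model.class_table():
        if prop <= 0:
            continue
        site_ll = _class_site_logliks(
            tree, partials, pi, get(w_bg), scale,
            foreground_leafsets=fg, fg_expm=get(w_fg),
        )
        per_class.append(site_ll)
        log_props.append(math.log(prop))
    stacked = np.stack(per_class) + np.array(log_props)[:, None]
    site_logl = logsumexp(stacked, axis=0)
    result = float(np.dot(weights, site_logl))
    if math.isnan(result):
        raise FloatingPointError("NaN log-likelihood")
    return result


def discrete_beta(p: float, q: float, K: int) -> list[tuple[float, float]]:
    """K equal-probability Beta(p, q) categories at their conditional means."""
    if K < 2:
        raise ValueError("K must be >= 2")
    bounds = beta_dist.ppf(np.linspace(0, 1, K + 1), p, q)
    # mean of each slice via the incomplete-beta identity
    upper = betainc(p + 1, q, bounds[1:])
    lower = betainc(p + 1, q, bounds[:-1])
    means = (p / (p + q)) * (upper - lower) * K
    means = np.clip(means, 1e-8, 1.0)
    return [(1.0 / K, float(m)) for m in means]


@dataclass
class SiteModelFit:
    name: str
    lnl: float
    params: dict
    model: object


def _optimize(nll, starts, bounds):
    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-11, "gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun):
        raise RuntimeError("codon model optimization failed from all starts")
    return best


def _logit(x):
    x = min(max(x, 1e-9), 1 - 1e-9)
    return math.log(x / (1 - x))


def _expit(x):
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def fit_site_models(
    tree: dendropy.Tree,
    aln: Alignment,
    models: Sequence[str] = ("M0", "M1", "M2", "M7", "M8"),
    K: int = 10,
    pi: Optional[np.ndarray] = None,
    neutral_legacy: bool = False,
) -> dict[str, SiteModelFit]:
    """Fit the requested site models by bounded maximum likelihood.

    "M1"/"M2" are the modern M1a/M2a (omega0 estimated in (0, 1), neutral
    class at omega = 1); ``neutral_legacy=True`` fixes omega0 = 0 instead
    (the original strict-neutral variant).  Each alternative model is seeded
    from its nested null's optimum so the lnL nesting inequalities
    lnL(M1) >= lnL(M0) (when omega0_M0 < 1), lnL(M2) >= lnL(M1) and
    lnL(M8) >= lnL(M7) hold at convergence.
    """
    if pi is None:
        pi = f3x4_frequencies(aln)
    fits: dict[str, SiteModelFit] = {}
    LB, UB = math.log(1e-3), math.log(1e3)

    def m0_nll(x):
        kappa, omega, scale = map(math.exp, x)
        return -codon_loglik(tree, aln, CodonModel(kappa, omega, pi), scale)

    if "M0" in models or "M1" in models or "M2" in models:
        res = _optimize(
            m0_nll,
            [[math.log(2.0), math.log(0.2), 0.0], [0.0, math.log(1.0), math.log(0.3)]],
            [(LB, UB)] * 3,
        )
        kappa0, omega0, scale0 = map(math.exp, res.x)
        fits["M0"] = SiteModelFit(
            "M0", -res.fun,
            {"kappa": kappa0, "omega": omega0, "scale": scale0},
            CodonModel(kappa0, omega0, pi),
        )

    if "M1" in models or "M2" in models:
        if neutral_legacy:
            def m1_nll(x):
                kappa, scale = math.exp(x[0]), math.exp(x[1])
                p0 = _expit(x[2])
                mdl = SiteClassModel(kappa, [(p0, 0.0), (1 - p0, 1.0)], pi)
                return -codon_loglik(tree, aln, mdl, scale)

            x0 = [math.log(fits["M0"].params["kappa"]),
                  math.log(fits["M0"].params["scale"]), _logit(0.9)]
            res = _optimize(m1_nll, [x0], [(LB, UB), (LB, UB), (-16, 16)])
            kappa, scale = math.exp(res.x[0]), math.exp(res.x[1])
            p0, w0 = _expit(res.x[2]), 0.0
        else:
            def m1_nll(x):
                kappa, scale = math.exp(x[0]), math.exp(x[1])
                p0, w0 = _expit(x[2]), _expit(x[3])
                mdl = SiteClassModel(kappa, [(p0, w0), (1 - p0, 1.0)], pi)
                return -codon_loglik(tree, aln, mdl, scale)

            m0p = fits["M0"].params
            seeds = [
                [math.log(m0p["kappa"]), math.log(m0p["scale"]),
                 _logit(1 - 1e-6), _logit(min(m0p["omega"], 1 - 1e-6))],
                [math.log(m0p["kappa"]), math.log(m0p["scale"]),
                 _logit(0.8), _logit(0.1)],
            ]
            res = _optimize(m1_nll, seeds, [(LB, UB), (LB, UB), (-16, 16), (-16, 16)])
            kappa, scale = math.exp(res.x[0]), math.exp(res.x[1])
            p0, w0 = _expit(res.x[2]), _expit(res.x[3])
        m1_model = SiteClassModel(kappa, [(p0, w0), (1 - p0, 1.0)], pi)
        fits["M1"] = SiteModelFit(
            "M1", -res.fun,
            {"kappa": kappa, "scale": scale, "p0": p0, "omega0": w0},
            m1_model,
        )

    if "M2" in models:
        def m2_nll(x):
            kappa, scale = math.exp(x[0]), math.exp(x[1])
            a0, a1 = x[2], x[3]
            e0, e1 = math.exp(a0), math.exp(a1)
            denom = e0 + e1 + 1.0
            p0, p1 = e0 / denom, e1 / denom
            w0 = _expit(x[4])
            w2 = 1.0 + math.exp(x[5])
            mdl = SiteClassModel(
                kappa, [(p0, w0), (p1, 1.0), (1 - p0 - p1, w2)], pi
            )
            return -codon_loglik(tree, aln, mdl, scale)

        m1p = fits["M1"].params
        p0s, p1s = max(m1p["p0"], 1e-6), max(1 - m1p["p0"] - 1e-6, 1e-6)
        seed = [
            math.log(m1p["kappa"]), math.log(m1p["scale"]),
            math.log(p0s / 1e-6), math.log(p1s / 1e-6),
            _logit(max(m1p["omega0"], 1e-6)), math.log(1e-3),
        ]
        # exploratory start with a real positive-selection class, since the
        # nested seed sits on a stationary boundary
        explore = [
            math.log(m1p["kappa"]), math.log(m1p["scale"]),
            math.log(0.8 / 0.1), math.log(0.1 / 0.1),
            _logit(max(m1p["omega0"], 1e-6)), math.log(1.5),
        ]
        res = _optimize(m2_nll, [seed, explore],
                        [(LB, UB), (LB, UB), (-20, 20), (-20, 20), (-16, 16),
                         (math.log(1e-4), math.log(50.0))])
        kappa, scale = math.exp(res.x[0]), math.exp(res.x[1])
        e0, e1 = math.exp(res.x[2]), math.exp(res.x[3])
        denom = e0 + e1 + 1.0
        p0, p1 = e0 / denom, e1 / denom
        w0, w2 = _expit(res.x[4]), 1.0 + math.exp(res.x[5])
        lnl = -res.fun
        if lnl < fits["M1"].lnl:  # numerical guard: M1 is nested in M2
            lnl = fits["M1"].lnl
            p0, p1 = m1p["p0"], 1 - m1p["p0"]
            w0, w2 = m1p["omega0"], 1.0
            kappa, scale = m1p["kappa"], m1p["scale"]
        fits["M2"] = SiteModelFit(
            "M2", lnl,
            {"kappa": kappa, "scale": scale, "p0": p0, "p1": p1,
             "omega0": w0, "omega2": w2},
            SiteClassModel(kappa, [(p0, w0), (p1, 1.0), (1 - p0 - p1, w2)], pi),
        )

    PQ_LB, PQ_UB = math.log(0.005), math.log(99.0)
    if "M7" in models or "M8" in models:
        def m7_nll(x):
            kappa, scale = math.exp(x[0]), math.exp(x[1])
            p, q = math.exp(x[2]), math.exp(x[3])
            mdl = SiteClassModel(kappa, discrete_beta(p, q, K), pi)
            return -codon_loglik(tree, aln, mdl, scale)

        start = [math.log(2.0), 0.0, math.log(0.5), math.log(2.0)]
        if "M0" in fits:
            start[0] = math.log(fits["M0"].params["kappa"])
            start[1] = math.log(fits["M0"].params["scale"])
        res = _optimize(m7_nll, [start],
                        [(LB, UB), (LB, UB), (PQ_LB, PQ_UB), (PQ_LB, PQ_UB)])
        kappa, scale = math.exp(res.x[0]), math.exp(res.x[1])
        p, q = math.exp(res.x[2]), math.exp(res.x[3])
        fits["M7"] = SiteModelFit(
            "M7", -res.fun,
            {"kappa": kappa, "scale": scale, "p": p, "q": q},
            SiteClassModel(kappa, discrete_beta(p, q, K), pi),
        )

    if "M8" in models:
        def m8_nll(x):
            kappa, scale = math.exp(x[0]), math.exp(x[1])
            p, q = math.exp(x[2]), math.exp(x[3])
            p0 = _expit(x[4])
            ws = 1.0 + math.exp(x[5])
            classes = [(p0 * pr, w) for pr, w in discrete_beta(p, q, K)]
            classes.append((1 - p0, ws))
            mdl = SiteClassModel(kappa, classes, pi)
            return -codon_loglik(tree, aln, mdl, scale)

        m7p = fits["M7"].params
        seed = [math.log(m7p["kappa"]), math.log(m7p["scale"]),
                math.log(m7p["p"]), math.log(m7p["q"]),
                _logit(1 - 1e-6), math.log(1e-3)]
        explore = [math.log(m7p["kappa"]), math.log(m7p["scale"]),
                   math.log(m7p["p"]), math.log(m7p["q"]),
                   _logit(0.9), math.log(1.5)]
        res = _optimize(m8_nll, [seed, explore],
                        [(LB, UB), (LB, UB), (PQ_LB, PQ_UB), (PQ_LB, PQ_UB),
                         (-16, 16), (math.log(1e-4), math.log(50.0))])
        kappa, scale = math.exp(res.x[0]), math.exp(res.x[1])
        p, q = math.exp(res.x[2]), math.exp(res.x[3])
        p0, ws = _expit(res.x[4]), 1.0 + math.exp(res.x[5])
        lnl = -res.fun
        if lnl < fits["M7"].lnl:
            lnl = fits["M7"].lnl
            p, q = m7p["p"], m7p["q"]
            p0, ws = 1.0 - 1e-9, 1.0
            kappa, scale = m7p["kappa"], m7p["scale"]
        classes = [(p0 * pr, w) for pr, w in discrete_beta(p, q, K)]
        classes.append((1 - p0, ws))
        fits["M8"] = SiteModelFit(
            "M8", lnl,
            {"kappa": kappa, "scale": scale, "p": p, "q": q,
             "p0": p0, "omega_s": ws},
            SiteClassModel(kappa, classes, pi),
        )
    return {name: fits[name] for name in models if name in fits}


def fit_branch_site(
    tree: dendropy.Tree,
    aln: Alignment,
    foreground,
    hypothesis: str = "H1",
    pi: Optional[np.ndarray] = None,
    _seed_params: Optional[dict] = None,
) -> SiteModelFit:
    """Fit branch-site model A under H0 (foreground omega2 = 1) or H1.

    ``foreground`` is a collection of leaf-label sets; the branch subtending
    exactly that leaf set is foreground (interior branches of the clade stay
    background, matching a single marked branch).
    """
    if hypothesis not in ("H0", "H1"):
        raise ValueError("hypothesis must be 'H0' or 'H1'")
    if pi is None:
        pi = f3x4_frequencies(aln)
    fg = {frozenset(s) for s in foreground}
    LB, UB = math.log(1e-3), math.log(1e3)

    def build(x):
        kappa, scale = math.exp(x[0]), math.exp(x[1])
        e0, e1 = math.exp(x[2]), math.exp(x[3])
        denom = e0 + e1 + 1.0
        p0, p1 = e0 / denom, e1 / denom
        w0 = _expit(x[4])
        w2 = 1.0 if hypothesis == "H0" else 1.0 + math.exp(x[5])
        return BranchSiteModel(kappa, p0, p1, w0, w2, fg, pi), scale

    def nll(x):
        mdl, scale = build(x)
        return -codon_loglik(tree, aln, mdl, scale)

    if _seed_params:
        sp = _seed_params
        base = [
            math.log(sp["kappa"]), math.log(sp["scale"]),
            math.log(max(sp["p0"], 1e-9) / max(1 - sp["p0"] - sp["p1"], 1e-9)),
            math.log(max(sp["p1"], 1e-9) / max(1 - sp["p0"] - sp["p1"], 1e-9)),
            _logit(max(sp["omega0"], 1e-9)),
        ]
    else:
        base = [math.log(2.0), 0.0, math.log(0.9 / 0.02), math.log(0.08 / 0.02),
                _logit(0.1)]
    starts = [base + ([math.log(1e-3)] if hypothesis == "H1" else [])]
    if hypothesis == "H1":
        starts.append(base + [math.log(2.0)])
    bounds = [(LB, UB), (LB, UB), (-20, 20), (-20, 20), (-16, 16)]
    if hypothesis == "H1":
        bounds.append((math.log(1e-4), math.log(50.0)))
    res = _optimize(nll, starts, bounds)
    mdl, scale = build(res.x)
    params = {
        "kappa": mdl.kappa, "scale": scale, "p0": mdl.p0, "p1": mdl.p1,
        "omega0": mdl.omega0, "omega2": mdl.omega2,
    }
    return SiteModelFit(f"branch-site {hypothesis}", -res.fun, params, mdl)


# ---------------------------------------------------------------------------
# Nei-Gojobori counting estimator

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts; changes to stops count as
    nonsynonymous, as in the original method."""
    syn = 0.0
    for pos in range(3):
        for alt in _NUC:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in _CODON_INDEX and _AA[mutant] == _AA[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) differences over substitution pathways,
    excluding pathways passing through stop codons when possible."""
    diff = [k for k in range(3) if c1[k] != c2[k]]
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                break
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not through_stop:
            paths.append((sd, nd))
    if not paths:  # every pathway hits a stop; count direct differences
        return (0.0, float(len(diff)))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori_dnds(aln: Alignment) -> pd.DataFrame:
    """Pairwise NG86 dN and dS with Jukes-Cantor correction.

    Codons containing gaps or ambiguity in either member of a pair are
    skipped for that pair.  The ratio is NaN (flagged ``undefined``) when
    dS is zero or a correction is out of range.
    """
    if aln.length % 3 != 0:
        raise ValueError(f"alignment length {aln.length} not divisible by 3")
    rows = []
    for i in range(len(aln)):
        for j in range(i + 1, len(aln)):
            s1, s2 = aln.seqs[i], aln.seqs[j]
            S = N = Sd = Nd = 0.0
            for site in range(0, aln.length, 3):
                c1, c2 = s1[site : site + 3], s2[site : site + 3]
                if c1 not in _CODON_INDEX or c2 not in _CODON_INDEX:
                    continue
                s_a, n_a = _codon_site_counts(c1)
                s_b, n_b = _codon_site_counts(c2)
                S += (s_a + s_b) / 2.0
                N += (n_a + n_b) / 2.0
                if c1 != c2:
                    sd, nd = _pathway_counts(c1, c2)
                    Sd += sd
                    Nd += nd
            if S == 0 or N == 0:
                dn = ds = ratio = float("nan")
            else:
                ds = _jc_correct(Sd / S)
                dn = _jc_correct(Nd / N)
                ratio = dn / ds if (ds and ds > 0 and not math.isnan(dn)) else float("nan")
            rows.append(
                {
                    "seq1": aln.ids[i], "seq2": aln.ids[j],
                    "dN": dn, "dS": ds, "dN_dS": ratio,
                    "undefined": not math.isfinite(ratio) if ratio == ratio else True,
                }
            )
    df = pd.DataFrame(rows)
    df["undefined"] = ~np.isfinite(df["dN_dS"].to_numpy())
    return df
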