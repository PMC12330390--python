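"""Bayesian inference of discrete-state transition rates on a phylogeny.

Implements the MultiState / Mk workflow used to estimate how often soda-lake
microbial lineages moved between continents over their evolutionary history:

* a continuous-time Markov chain over K discrete states (continents) with an
  arbitrary rate matrix Q, optionally constrained (rates tied pairwise equal,
  or fixed to zero);
* Felsenstein pruning for the likelihood of ambiguity-coded tip states;
* Metropolis-Hastings MCMC over the free rates under uniform, exponential,
  gamma priors or their hyper-prior versions;
* stepping-stone estimation of the log marginal likelihood for model
  comparison by log-Bayes factors;
* Gelman-Rubin congruence diagnostics across repeated runs.

States are continents here, but nothing in the engine is specific to
biogeography: any discrete character with two or more states fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.special import gammaln, logsumexp

from .errors import InvalidArgumentError
from .trees import Phylogeny

__all__ = [
    "RateModel",
    "TipStateMatrix",
    "PriorSpec",
    "McmcConfig",
    "McmcTrace",
    "SteppingStoneResult",
    "transition_probabilities",
    "pruning_log_likelihood",
    "mcmc_sample",
    "stepping_stone_logml",
    "compare_models",
    "encode_tip_states",
    "run_congruence",
    "scale_tree",
]

# re-export: tree scaling is part of the transition workflow
from .trees import scale_tree  # noqa: E402,F401


# ======================================================================
# model containers
# ======================================================================

FREE = "free"
ZERO = "zero"


@dataclass(frozen=True)
class RateModel:
    """K-state rate matrix with a constraint mask.

    ``rates`` maps each ordered state pair (i, j), i != j, to a
    non-negative instantaneous rate q_ij.  ``constraints`` maps a pair to
    ``"free"`` (its own parameter), ``"zero"`` (fixed at 0), or
    ``("tie", (k, l))`` (shares the parameter of the free pair (k, l)).
    The generator matrix has rows summing to zero by construction.
    """

    n_states: int
    rates: dict = None  # type: ignore[assignment]
    constraints: dict = None  # type: ignore[assignment]
    root_frequencies: np.ndarray = None  # type: ignore[assignment]
    state_names: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        K = self.n_states
        if K < 2:
            raise InvalidArgumentError("need at least 2 states")
        pairs = [(i, j) for i in range(K) for j in range(K) if i != j]
        cons = dict(self.constraints) if self.constraints else {}
        for p in pairs:
            cons.setdefault(p, FREE)
        for p, c in cons.items():
            if isinstance(c, tuple) and c[0] == "tie":
                tgt = tuple(c[1])
                if cons.get(tgt) != FREE:
                    raise InvalidArgumentError(f"tie target {tgt} of {p} must be a free pair")
        rates = dict(self.rates) if self.rates else {}
        for p in pairs:
            rates.setdefault(p, 1.0)
            if rates[p] < 0:
                raise InvalidArgumentError(f"negative rate for pair {p}")
        rf = self.root_frequencies
        rf = np.full(K, 1.0 / K) if rf is None else np.asarray(rf, dtype=float)
        if rf.shape != (K,) or np.any(rf < 0) or abs(rf.sum() - 1.0) > 1e-8:
            raise InvalidArgumentError("root_frequencies must be a probability vector of length K")
        names = self.state_names or tuple(f"S{i}" for i in range(K))
        if len(names) != K:
            raise InvalidArgumentError("state_names length must equal n_states")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "constraints", cons)
        object.__setattr__(self, "root_frequencies", rf)
        object.__setattr__(self, "state_names", tuple(names))

    # ---------------------------------------------------------------- structure
    @property
    def ordered_pairs(self) -> list:
        K = self.n_states
        return [(i, j) for i in range(K) for j in range(K) if i != j]

    @property
    def free_pairs(self) -> list:
        return [p for p in self.ordered_pairs if self.constraints[p] == FREE]

    @property
    def n_free(self) -> int:
        return len(self.free_pairs)

    def pair_label(self, pair) -> str:
        i, j = pair
        return f"q({self.state_names[i]}->{self.state_names[j]})"

    def _free_map(self) -> np.ndarray:
        """Per ordered pair: index into the free-parameter vector, or -1 for zero."""
        idx = {p: k for k, p in enumerate(self.free_pairs)}
        out = np.empty(len(self.ordered_pairs), dtype=np.int64)
        for m, p in enumerate(self.ordered_pairs):
            c = self.constraints[p]
            if c == FREE:
                out[m] = idx[p]
            elif c == ZERO:
                out[m] = -1
            else:
                out[m] = idx[tuple(c[1])]
        return out

    # ---------------------------------------------------------------- values
    def free_values(self) -> np.ndarray:
        return np.array([self.rates[p] for p in self.free_pairs], dtype=float)

    def q_vector(self, free_values: np.ndarray | None = None) -> np.ndarray:
        theta = self.free_values() if free_values is None else np.asarray(free_values, float)
        fmap = self._free_map()
        q = np.where(fmap >= 0, theta[np.maximum(fmap, 0)], 0.0)
        return q

    def generator(self, free_values: np.ndarray | None = None) -> np.ndarray:
        q = self.q_vector(free_values)
        K = self.n_states
        Q = np.zeros((K, K))
        for m, (i, j) in enumerate(self.ordered_pairs):
            Q[i, j] = q[m]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def with_free_values(self, theta: np.ndarray) -> "RateModel":
        rates = dict(self.rates)
        fmap = self._free_map()
        for m, p in enumerate(self.ordered_pairs):
            rates[p] = float(theta[fmap[m]]) if fmap[m] >= 0 else 0.0
        return replace(self, rates=rates)

    # ---------------------------------------------------------------- constraint builders
    def tie_symmetric(self) -> "RateModel":
        """Constrain q_ij = q_ji for every unordered pair (the symmetric model)."""
        cons = dict(self.constraints)
        for i in range(self.n_states):
            for j in range(i + 1, self.n_states):
                if cons[(i, j)] == FREE and cons[(j, i)] == FREE:
                    cons[(j, i)] = ("tie", (i, j))
        return replace(self, constraints=cons)

    def with_zero(self, *pairs) -> "RateModel":
        """Fix the given ordered pairs' rates to zero."""
        cons = dict(self.constraints)
        for p in pairs:
            p = tuple(p)
            for other, c in cons.items():
                if isinstance(c, tuple) and tuple(c[1]) == p:
                    raise InvalidArgumentError(f"pair {p} is a tie target of {other}; untie first")
            cons[p] = ZERO
        return replace(self, constraints=cons)

    def with_equal_rates(self) -> "RateModel":
        """Single shared rate for every ordered pair (the equal-rates Mk model)."""
        first = self.ordered_pairs[0]
        cons = {p: ("tie", first) for p in self.ordered_pairs}
        cons[first] = FREE
        return replace(self, constraints=cons)


@dataclass
class TipStateMatrix:
    """Per-tip 0/1 state-compatibility vectors (ambiguity coding).

    A row of all ones means the tip is fully ambiguous; each row must have
    at least one 1.
    """

    tip_labels: list
    matrix: np.ndarray
    state_names: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.tip_labels):
            raise InvalidArgumentError("matrix must be (n_tips, K)")
        if np.any((self.matrix != 0) & (self.matrix != 1)):
            raise InvalidArgumentError("tip state entries must be 0 or 1")
        if np.any(self.matrix.sum(axis=1) < 1):
            raise InvalidArgumentError("every tip needs at least one compatible state")
        if self.state_names is None:
            self.state_names = tuple(f"S{i}" for i in range(self.matrix.shape[1]))

    @property
    def n_states(self) -> int:
        return self.matrix.shape[1]

    def reordered(self, labels) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.tip_labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise InvalidArgumentError(f"tip states missing for tree leaves: {missing[:5]}")
        return self.matrix[[index[lab] for lab in labels]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.astype(int), index=self.tip_labels,
                            columns=list(self.state_names))


# ======================================================================
# transition probabilities and pruning likelihood
# ======================================================================

def transition_probabilities(model: RateModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt): the K x K matrix of state-change probabilities over time t."""
    if t < 0 or not math.isfinite(t):
        raise InvalidArgumentError("branch length t must be non-negative and finite")
    Q = model.generator()
    P = _edge_probabilities(Q, np.array([float(t)]))[0]
    return P


def _edge_probabilities(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q * t_e) for every edge length, vectorized via eigendecomposition.

    Falls back to scaling-and-squaring (scipy expm) per edge when Q is
    defective or the eigendecomposition reconstruction is inaccurate.
    Rows are clipped to [0, inf) and renormalized to sum to exactly 1.
    """
    K = Q.shape[0]
    P = None
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        ew = np.exp(np.multiply.outer(lengths, w))  # (E, K)
        P = np.einsum("ik,ek,kj->eij", V, ew, Vinv).real
        # near-defective Q loses accuracy; cross-check the longest edge
        # (where eigendecomposition error is largest) against expm
        e_max = int(np.argmax(lengths))
        if np.max(np.abs(P[e_max] - expm(Q * lengths[e_max]))) > 1e-12:
            P = None
    except np.linalg.LinAlgError:
        P = None
    if P is None or not np.all(np.isfinite(P)) or np.any(np.abs(P.sum(axis=2) - 1.0) > 1e-8):
        P = np.stack([expm(Q * t) for t in lengths])
    P = np.clip(P, 0.0, None)
    rows = P.sum(axis=2, keepdims=True)
    if np.any(np.abs(rows - 1.0) > 1e-6):
        raise FloatingPointError("transition matrix rows failed to normalize")
    P /= rows
    return P


class MkLikelihood:
    """Felsenstein pruning likelihood bound to one (tree, tip states) pair.

    Precomputes the traversal order and the tip partials once; each call
    costs one eigendecomposition of Q plus a vectorized edge-probability
    build and a post-order sweep.
    """

    def __init__(self, tree: Phylogeny, tips: TipStateMatrix):
        self.tree = tree
        self.n_states = tips.n_states
        self.tip_partials = tips.reordered(tree.tip_labels)
        self.postorder = tree.postorder_internal
        self.children = [np.asarray(c, dtype=np.int64) for c in tree.children]
        self.edge_length = tree.edge_length
        # binary trees admit a level-vectorized sweep: group internal nodes
        # by the height of their subtree so each level is one batched update
        self._levels = None
        if all(len(c) in (0, 2) for c in tree.children):
            depth = np.zeros(tree.n_nodes, dtype=np.int64)
            for node in self.postorder:
                depth[node] = 1 + max(depth[c] for c in tree.children[node])
            levels = []
            for d in range(1, depth.max() + 1):
                nodes = np.where(depth == d)[0]
                nodes = nodes[nodes >= tree.n_tips] if d == 1 else nodes
                nodes = np.asarray([n for n in nodes if tree.children[n]], dtype=np.int64)
                if len(nodes):
                    c1 = np.asarray([tree.children[n][0] for n in nodes])
                    c2 = np.asarray([tree.children[n][1] for n in nodes])
                    levels.append((nodes, c1, c2))
            self._levels = levels

    def __call__(self, Q: np.ndarray, root_frequencies: np.ndarray) -> float:
        tree = self.tree
        K = self.n_states
        P = _edge_probabilities(Q, self.edge_length)
        partial = np.empty((tree.n_nodes, K))
        partial[: tree.n_tips] = self.tip_partials
        log_scale = 0.0
        if self._levels is not None:
            for nodes, c1, c2 in self._levels:
                prod = (np.einsum("nij,nj->ni", P[c1], partial[c1])
                        * np.einsum("nij,nj->ni", P[c2], partial[c2]))
                s = prod.max(axis=1)
                if not np.all(s > 0.0):
                    return float("-inf")
                partial[nodes] = prod / s[:, None]
                log_scale += float(np.log(s).sum())
        else:
            children = self.children
            for node in self.postorder:
                kids = children[node]
                prod = P[kids[0]] @ partial[kids[0]]
                for c in kids[1:]:
                    prod = prod * (P[c] @ partial[c])
                s = prod.max()
                if not (s > 0.0):
                    return float("-inf")
                partial[node] = prod / s
                log_scale += math.log(s)
        L = float(root_frequencies @ partial[tree.root])
        if L <= 0.0:
            return float("-inf")
        return math.log(L) + log_scale


def pruning_log_likelihood(tree: Phylogeny, tips: TipStateMatrix,
                           model: RateModel) -> float:
    """Natural-log likelihood of the tip states under ``model`` on ``tree``.

    Returns -inf when the data are impossible under the model (e.g. a
    required transition has its rate constrained to zero).
    """
    if tips.n_states != model.n_states:
        raise InvalidArgumentError("tip-state K and model K differ")
    return MkLikelihood(tree, tips)(model.generator(), model.root_frequencies)


# ======================================================================
# priors
# ======================================================================

_BASE_FAMILIES = ("uniform", "exponential", "gamma")


@dataclass(frozen=True)
class PriorSpec:
    """Prior on each free transition rate.

    families: ``uniform(lo, hi)``, ``exponential(mean)``, ``gamma(shape,
    scale)``, and hyper-prior versions (``hyper-*``) in which the prior's
    parameters are themselves sampled, each uniformly on ``hyper_range``,
    as extra MCMC dimensions.
    """

    family: str = "gamma"
    params: tuple = None  # type: ignore[assignment]
    hyper_range: tuple = (0.0, 10.0)

    def __post_init__(self) -> None:
        fam = self.family
        base = fam[6:] if fam.startswith("hyper-") else fam
        if base not in _BASE_FAMILIES:
            raise InvalidArgumentError(f"unknown prior family {fam!r}")
        if self.params is None:
            defaults = {"uniform": (0.0, 100.0), "exponential": (1.0,),
                        "gamma": (1.0, 1.0)}
            object.__setattr__(self, "params", defaults[base])
        lo, hi = self.hyper_range
        if not (hi > lo >= 0):
            raise InvalidArgumentError("hyper_range must satisfy 0 <= lo < hi")

    @property
    def base_family(self) -> str:
        return self.family[6:] if self.is_hyper else self.family

    @property
    def is_hyper(self) -> bool:
        return self.family.startswith("hyper-")

    @property
    def n_hyper(self) -> int:
        if not self.is_hyper:
            return 0
        return {"uniform": 1, "exponential": 1, "gamma": 2}[self.base_family]

    def _effective_params(self, hyper: np.ndarray | None) -> tuple:
        if not self.is_hyper:
            return self.params
        base = self.base_family
        if base == "uniform":
            # hyper parameter is the upper bound; lower bound pinned at 0
            return (0.0, float(hyper[0]))
        if base == "exponential":
            return (float(hyper[0]),)
        return (float(hyper[0]), float(hyper[1]))

    def log_density(self, rates: np.ndarray, hyper: np.ndarray | None = None) -> float:
        """Sum of log prior densities over the free rates."""
        rates = np.asarray(rates, float)
        base = self.base_family
        p = self._effective_params(hyper)
        if base == "uniform":
            lo, hi = p
            if hi <= lo:
                return float("-inf")
            if np.any(rates < lo) or np.any(rates > hi):
                return float("-inf")
            return -len(rates) * math.log(hi - lo)
        if np.any(rates <= 0):
            return float("-inf")
        if base == "exponential":
            mean = p[0]
            if mean <= 0:
                return float("-inf")
            return float(-len(rates) * math.log(mean) - rates.sum() / mean)
        shape, scale = p
        if shape <= 0 or scale <= 0:
            return float("-inf")
        return float(((shape - 1) * np.log(rates) - rates / scale).sum()
                     - len(rates) * (shape * math.log(scale) + gammaln(shape)))

    def hyper_log_density(self, hyper: np.ndarray | None) -> float:
        if not self.is_hyper:
            return 0.0
        lo, hi = self.hyper_range
        h = np.asarray(hyper, float)
        if np.any(h <= lo) or np.any(h >= hi):
            return float("-inf")
        return -self.n_hyper * math.log(hi - lo)

    def sample_rates(self, n: int, rng: np.random.Generator,
                     hyper: np.ndarray | None = None) -> np.ndarray:
        base = self.base_family
        p = self._effective_params(hyper)
        if base == "uniform":
            return rng.uniform(p[0], p[1], size=n)
        if base == "exponential":
            return rng.exponential(p[0], size=n)
        return rng.gamma(p[0], p[1], size=n)

    def initial_hyper(self, rng: np.random.Generator) -> np.ndarray | None:
        if not self.is_hyper:
            return None
        lo, hi = self.hyper_range
        return rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo),
                           size=self.n_hyper)


# ======================================================================
# MCMC
# ======================================================================

@dataclass(frozen=True)
class McmcConfig:
    """Chain-length settings.

    The default (100,000 iterations, 10,000 burn-in, thinning 10) is a
    desk-scale setting; :meth:`paper_mode` returns the production setting
    of 10,100,000 iterations with 100,000 burn-in sampled every 1,000.
    """

    iterations: int = 100_000
    burn_in: int = 10_000
    thinning: int = 10
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise InvalidArgumentError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise InvalidArgumentError("thinning must be >= 1")

    @classmethod
    def paper_mode(cls, seed: int = 0, n_chains: int = 3) -> "McmcConfig":
        return cls(iterations=10_100_000, burn_in=100_000, thinning=1_000,
                   n_chains=n_chains, seed=seed)


@dataclass
class McmcTrace:
    """Posterior samples of the free rates (plus hyper-parameters if any)."""

    free: np.ndarray              # (n_samples, n_free)
    log_likelihood: np.ndarray    # (n_samples,)
    pair_labels: list
    hyper: np.ndarray | None = None
    acceptance_rate: float = float("nan")

    def rates_frame(self, model: RateModel) -> pd.DataFrame:
        """Expand to the full ordered-pair rate table (ties/zeros applied)."""
        cols = {}
        fmap = model._free_map()
        for m, p in enumerate(model.ordered_pairs):
            col = model.pair_label(p)
            cols[col] = self.free[:, fmap[m]] if fmap[m] >= 0 else np.zeros(len(self.free))
        out = pd.DataFrame(cols)
        out["log_likelihood"] = self.log_likelihood
        return out

    def summary(self, model: RateModel) -> pd.DataFrame:
        """Posterior median and central 95% credible interval per free rate."""
        med = np.median(self.free, axis=0)
        lo = np.quantile(self.free, 0.025, axis=0)
        hi = np.quantile(self.free, 0.975, axis=0)
        return pd.DataFrame({"parameter": self.pair_labels, "median": med,
                             "ci_2.5%": lo, "ci_97.5%": hi})


class _Sampler:
    """Random-scan Metropolis-Hastings over free rates (and hyper-parameters).

    Rates move by multiplicative log-space random walks (with the q'/q
    Hastings correction); hyper-parameters by additive Gaussian steps
    rejected outside their uniform range.  Per-parameter step sizes adapt
    toward a 0.2-0.4 acceptance rate while ``adapt=True`` and are frozen
    afterwards to preserve detailed balance.
    """

    def __init__(self, like: MkLikelihood, model: RateModel, prior: PriorSpec,
                 rng: np.random.Generator, power: float = 1.0):
        self.like = like
        self.model = model
        self.prior = prior
        self.rng = rng
        self.power = power
        self.n_free = model.n_free
        if self.n_free == 0:
            raise InvalidArgumentError("model has no free parameters to sample")
        self.hyper = prior.initial_hyper(rng)
        theta = np.clip(prior.sample_rates(self.n_free, rng, self.hyper), 1e-4, 10.0)
        self.theta = theta
        self.root_freq = model.root_frequencies
        self._fmap = model._free_map()
        self._pairs = model.ordered_pairs
        self._K = model.n_states
        self.log_prior = (prior.log_density(theta, self.hyper)
                          + prior.hyper_log_density(self.hyper))
        if not np.isfinite(self.log_prior):
            raise InvalidArgumentError("prior excludes the initial state; check prior parameters")
        self.log_like = self._loglike(theta)
        n_dim = self.n_free + (prior.n_hyper if prior.is_hyper else 0)
        self.step = np.full(n_dim, 0.5)
        self.n_prop = np.zeros(n_dim)
        self.n_acc = np.zeros(n_dim)

    def _loglike(self, theta: np.ndarray) -> float:
        q = np.where(self._fmap >= 0, theta[np.maximum(self._fmap, 0)], 0.0)
        K = self._K
        Q = np.zeros((K, K))
        for m, (i, j) in enumerate(self._pairs):
            Q[i, j] = q[m]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return self.like(Q, self.root_freq)

    def sweep(self) -> None:
        """One update of a randomly chosen parameter."""
        rng = self.rng
        n_h = self.prior.n_hyper if self.prior.is_hyper else 0
        d = int(rng.integers(self.n_free + n_h))
        self.n_prop[d] += 1
        if d < self.n_free:
            theta = self.theta.copy()
            eps = rng.normal(0.0, self.step[d])
            theta[d] = self.theta[d] * math.exp(eps)
            log_hastings = math.log(theta[d] / self.theta[d])
            lp = (self.prior.log_density(theta, self.hyper)
                  + self.prior.hyper_log_density(self.hyper))
            if not np.isfinite(lp):
                return
            ll = self._loglike(theta)
            if math.log(rng.uniform()) < (self.power * (ll - self.log_like)
                                          + lp - self.log_prior + log_hastings):
                self.theta, self.log_like, self.log_prior = theta, ll, lp
                self.n_acc[d] += 1
        else:
            hyper = self.hyper.copy()
            k = d - self.n_free
            hyper[k] += rng.normal(0.0, self.step[d])
            lp = (self.prior.log_density(self.theta, hyper)
                  + self.prior.hyper_log_density(hyper))
            if not np.isfinite(lp):
                return
            if math.log(rng.uniform()) < lp - self.log_prior:
                self.hyper, self.log_prior = hyper, lp
                self.n_acc[d] += 1

    def adapt(self) -> None:
        """Retune per-parameter steps toward 0.2-0.4 acceptance, then reset counters."""
        for d in range(len(self.step)):
            if self.n_prop[d] < 10:
                continue
            rate = self.n_acc[d] / self.n_prop[d]
            if rate > 0.4:
                self.step[d] *= 1.4
            elif rate < 0.2:
                self.step[d] /= 1.4
            self.step[d] = min(max(self.step[d], 1e-3), 20.0)
        self.n_prop[:] = 0.0
        self.n_acc[:] = 0.0

    def run(self, n_iter: int, adapt: bool = False, adapt_every: int = 100,
            record_every: int = 0):
        """Run ``n_iter`` updates; optionally record every ``record_every``-th state."""
        theta_out, ll_out, hyper_out = [], [], []
        acc0, prop0 = self.n_acc.sum(), self.n_prop.sum()
        for it in range(1, n_iter + 1):
            self.sweep()
            if adapt and it % adapt_every == 0:
                self.adapt()
            if record_every and it % record_every == 0:
                theta_out.append(self.theta.copy())
                ll_out.append(self.log_like)
                if self.hyper is not None:
                    hyper_out.append(self.hyper.copy())
        accepted = self.n_acc.sum() - (acc0 if not adapt else 0.0)
        proposed = self.n_prop.sum() - (prop0 if not adapt else 0.0)
        rate = accepted / proposed if proposed else float("nan")
        return (np.array(theta_out), np.array(ll_out),
                np.array(hyper_out) if hyper_out else None, rate)


def mcmc_sample(tree: Phylogeny, tips: TipStateMatrix, model: RateModel,
                prior: PriorSpec | None = None,
                config: McmcConfig | None = None) -> McmcTrace:
    """Posterior sample of the free transition rates by Metropolis-Hastings.

    Before sampling, a built-in self-test verifies that the pruning kernel
    returns likelihood 1 for fully ambiguous tips (total-probability
    conservation); a failure indicates a numerically broken generator.
    """
    prior = prior or PriorSpec()
    config = config or McmcConfig()
    like = MkLikelihood(tree, tips)
    _ambiguity_self_test(like, model)
    rng = np.random.default_rng(config.seed)
    sampler = _Sampler(like, model, prior, rng)
    sampler.run(config.burn_in, adapt=True)
    theta, ll, hyper, rate = sampler.run(config.iterations - config.burn_in,
                                         record_every=config.thinning)
    labels = [model.pair_label(p) for p in model.free_pairs]
    return McmcTrace(free=theta, log_likelihood=ll, pair_labels=labels,
                     hyper=hyper, acceptance_rate=rate)


def _ambiguity_self_test(like: MkLikelihood, model: RateModel) -> None:
    ambiguous = np.ones_like(like.tip_partials)
    saved = like.tip_partials
    like.tip_partials = ambiguous
    try:
        ll = like(model.generator(), model.root_frequencies)
    finally:
        like.tip_partials = saved
    if abs(ll) > 1e-8:
        raise FloatingPointError(
            f"pruning self-test failed: ambiguous-tip log-likelihood {ll:g} != 0")


# ======================================================================
# stepping-stone marginal likelihood
# ======================================================================

@dataclass
class SteppingStoneResult:
    n_stones: int
    iterations_per_stone: int
    beta_schedule: np.ndarray      # descending, 1 -> 0
    log_marginal_likelihood: float
    per_stone_terms: np.ndarray = None  # type: ignore[assignment]
    failed: bool = False


def stepping_stone_logml(tree: Phylogeny, tips: TipStateMatrix, model: RateModel,
                         prior: PriorSpec | None = None, n_stones: int = 100,
                         iterations_per_stone: int = 1000, seed: int = 0,
                         schedule_alpha: float = 0.4,
                         burn_per_stone: int | None = None) -> SteppingStoneResult:
    """Stepping-stone estimate of the log marginal likelihood.

    The power-posterior temperatures follow the quantiles of Beta(alpha, 1)
    with alpha = 0.4, beta_k = (k / n_stones)^(1/alpha), crowding stones
    near the prior where the integrand changes fastest.  The chain starts
    at the posterior (beta = 1) and cools stone by stone; each stone k
    samples from density proportional to L^beta_k * prior and contributes
    log mean(L^(beta_{k-1} - beta_k)).  The telescoping sum over stones
    estimates log of the marginal likelihood Z = integral L * prior.
    """
    if n_stones < 2:
        raise InvalidArgumentError("need at least 2 stones")
    prior = prior or PriorSpec()
    like = MkLikelihood(tree, tips)
    _ambiguity_self_test(like, model)
    rng = np.random.default_rng(seed)
    betas = (np.arange(n_stones, -1, -1) / n_stones) ** (1.0 / schedule_alpha)
    if burn_per_stone is None:
        burn_per_stone = max(50, iterations_per_stone // 10)
    sampler = _Sampler(like, model, prior, rng, power=1.0)
    sampler.run(max(200, iterations_per_stone), adapt=True)  # warm up at the posterior
    terms = np.empty(n_stones)
    failed = False
    for k in range(1, n_stones + 1):
        beta_hi, beta_lo = betas[k - 1], betas[k]
        sampler.power = beta_lo
        sampler.run(burn_per_stone)
        _, ll, _, _ = sampler.run(iterations_per_stone, record_every=1)
        delta = beta_hi - beta_lo
        if not np.all(np.isfinite(ll)):
            failed = True
            terms[k - 1] = np.nan
            continue
        terms[k - 1] = logsumexp(delta * ll) - math.log(len(ll))
    logml = float(np.nansum(terms)) if not failed else float("nan")
    return SteppingStoneResult(n_stones=n_stones,
                               iterations_per_stone=iterations_per_stone,
                               beta_schedule=betas,
                               log_marginal_likelihood=logml,
                               per_stone_terms=terms, failed=failed)


def compare_models(logml_a: float, logml_b: float):
    """Log-Bayes factor of model a over model b.

    A difference of 10 log marginal-likelihood units is read as very
    strong evidence for one model over the other.
    """
    lbf = float(logml_a) - float(logml_b)
    if abs(lbf) >= 10.0:
        verdict = "very strong evidence for model " + ("a" if lbf > 0 else "b")
    else:
        verdict = "no very strong preference"
    return lbf, verdict


# ======================================================================
# tip-state encoding and run congruence
# ======================================================================

def encode_tip_states(abundance: pd.DataFrame,
                      ambiguity_threshold: float = 0.05) -> TipStateMatrix:
    """Ambiguity-code tips from per-species per-continent relative abundance.

    ``abundance``: species (rows) x continents (columns), any non-negative
    scale; rows are normalized to fractions.  Continent j is compatible
    with a species iff its abundance fraction is >= ``ambiguity_threshold``;
    a species below threshold everywhere gets its argmax continent.
    """
    if not 0 <= ambiguity_threshold <= 1:
        raise InvalidArgumentError("ambiguity_threshold must be in [0, 1]")
    values = abundance.to_numpy(dtype=float)
    if np.any(values < 0):
        raise InvalidArgumentError("abundances must be non-negative")
    totals = values.sum(axis=1)
    if np.any(totals == 0):
        bad = abundance.index[totals == 0].tolist()
        raise InvalidArgumentError(f"species with zero total abundance: {bad[:5]}")
    frac = values / totals[:, None]
    mat = (frac >= ambiguity_threshold).astype(float)
    empty = mat.sum(axis=1) == 0
    if empty.any():
        mat[np.where(empty)[0], frac[empty].argmax(axis=1)] = 1.0
    return TipStateMatrix(tip_labels=list(abundance.index), matrix=mat,
                          state_names=tuple(abundance.columns))


def run_congruence(traces: list, psrf_threshold: float = 1.1) -> pd.DataFrame:
    """Gelman-Rubin potential scale reduction factor across repeated runs.

    ``traces`` may be a list of :class:`McmcTrace` or of 2-D sample arrays
    with matching shapes.  A parameter passes when PSRF < ``psrf_threshold``
    (1.1 by convention); the run is congruent when all parameters pass.
    PSRF is floored at 1.0 so identical chains report exactly 1.
    """
    arrays = [t.free if isinstance(t, McmcTrace) else np.asarray(t, float)
              for t in traces]
    if len(arrays) < 2:
        raise InvalidArgumentError("congruence needs at least 2 runs")
    arrays = [a[:, None] if a.ndim == 1 else a for a in arrays]
    n = min(a.shape[0] for a in arrays)
    chains = np.stack([a[:n] for a in arrays])  # (m, n, p)
    m = chains.shape[0]
    means = chains.mean(axis=1)                 # (m, p)
    variances = chains.var(axis=1, ddof=1)      # (m, p)
    W = variances.mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n - 1) / n * W + B_over_n
        psrf = np.sqrt(var_hat / W)
    psrf = np.where(W == 0, np.where(B_over_n == 0, 1.0, np.inf), psrf)
    psrf = np.maximum(psrf, 1.0)
    labels = (traces[0].pair_labels if isinstance(traces[0], McmcTrace)
              else [f"param{i}" for i in range(chains.shape[2])])
    out = pd.DataFrame({"parameter": labels, "psrf": psrf,
                        "pass": psrf < psrf_threshold})
    out.attrs["congruent"] = bool(out["pass"].all())
    return out
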