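"""Metropolis–Hastings sampler over phylodynamic parameters, internal
node ages, fossil ages and (for the birth-death model) the origin age.

Topologies are fixed; the sampler jointly updates

* the model's scalar rates (multiplicative scale moves for positive
  parameters, sliding windows for real-valued growth rates),
* internal node ages (uniform between the oldest child and the parent,
  or the origin for the root),
* fossil tip and sampled-ancestor ages within their stratigraphic
  bounds (the uniform tip-age priors of tip dating), and
* the origin age, uniform between the current root age and the prior
  cap.

A single seeded generator drives every draw, so runs are bit-
reproducible. The chain extends in fixed-length chunks until the
post-burn-in effective sample size of every scalar parameter exceeds
the target (default 200), or a hard cap of chunks is reached.

Internally the tree lives in flat arrays (one age per node) so the
birth-death likelihood — a sum of independent per-node terms given the
rate workspace — can be updated in O(1) when a single age moves and
recomputed vectorised when the rates change. The running log-likelihood
is re-anchored by a from-scratch evaluation at every chunk boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coalescent import NTrajectory
from .core import (
    BDSKYParams,
    CoalescentParams,
    TimeGrid,
    TimeTree,
    ValidationError,
)
from .fbd import FBDWorkspace
from .moves import scale_move, window_move
from .priors import PriorSpec, default_priors
from .summary import ess as _ess

__all__ = ["MCMCConfig", "Trace", "run_mcmc"]


@dataclass
class MCMCConfig:
    """Sampler configuration.

    ``chain_length`` is the number of iterations per extension chunk;
    the chain runs whole chunks until the minimum post-burn-in ESS over
    scalar parameters exceeds ``target_ess`` or ``max_chunks`` is hit.
    """

    chain_length: int = 20_000
    thin: int = 20
    seed: int = 1
    target_ess: float = 200.0
    burn_in: float = 0.10
    max_chunks: int = 10
    scale_step: float = 0.7
    window_step: float = 0.4
    root_window: float = 20.0  # reflected-window width for a root with no origin
    adapt: bool = True  # diminishing Robbins-Monro tuning of the step sizes
    adapt_target: float = 0.30  # acceptance rate the tuning aims for
    move_weights: dict[str, float] = field(
        default_factory=lambda: {
            "rates": 0.4,
            "node_ages": 0.3,
            "tip_ages": 0.2,
            "origin": 0.1,
        }
    )
    prior_only: bool = False  # disable the likelihood (prior-sampling mode)

    def __post_init__(self) -> None:
        if self.chain_length <= 0:
            raise ValidationError("chain_length must be positive")
        if not 0.0 <= self.burn_in < 1.0:
            raise ValidationError("burn-in fraction must be in [0, 1)")
        if self.thin <= 0:
            raise ValidationError("thin must be positive")


@dataclass
class Trace:
    """Posterior sample: one row per retained iteration with the
    log-posterior decomposition, every scalar parameter, the origin and
    root ages, and each sampled fossil age."""

    records: pd.DataFrame
    model: str
    scalar_names: list[str]
    acceptance: dict[str, float]
    ess: dict[str, float]
    converged: bool

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path: str | Path) -> None:
        """Write a BEAST-style tab-separated log (state first column);
        floats keep 17 significant digits so the file round-trips
        bit-exactly."""
        self.records.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @staticmethod
    def read_tsv(path: str | Path) -> pd.DataFrame:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        required = {"state", "posterior", "likelihood", "prior"}
        if not required <= set(df.columns):
            raise ValidationError(
                f"trace {path} is missing required column(s): "
                f"{sorted(required - set(df.columns))}"
            )
        if len(df) == 0:
            raise ValidationError(f"trace {path} has no records")
        return df


class _TreeArrays:
    """Flat-array view of a fixed-topology tree.

    Preorder node indexing; ``kind`` is 2 for bifurcations, 1 for
    sampled ancestors, 0 for leaves. Sample bounds default to NaN
    (age fixed)."""

    def __init__(self, tree: TimeTree) -> None:
        nodes = list(tree.preorder())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.labels = [nd.label for nd in nodes]
        self.ages = np.array([nd.age for nd in nodes])
        self.parent = np.full(n, -1, dtype=np.int64)
        self.ch1 = np.full(n, -1, dtype=np.int64)
        self.ch2 = np.full(n, -1, dtype=np.int64)
        self.kind = np.zeros(n, dtype=np.int8)
        for i, nd in enumerate(nodes):
            self.kind[i] = len(nd.children)
            for j, ch in enumerate(nd.children):
                k = index[id(ch)]
                self.parent[k] = i
                if j == 0:
                    self.ch1[i] = k
                else:
                    self.ch2[i] = k
        self.bif_idx = np.flatnonzero(self.kind == 2)
        self.sa_idx = np.flatnonzero(self.kind == 1)
        self.leaf_idx = np.flatnonzero(self.kind == 0)
        self.lo_bound = np.full(n, np.nan)
        self.hi_bound = np.full(n, np.nan)
        for i, nd in enumerate(nodes):
            if self.kind[i] != 2 and nd.label in tree.tip_bounds:
                oldest, youngest = tree.tip_bounds[nd.label]
                if oldest > youngest:
                    self.lo_bound[i] = youngest
                    self.hi_bound[i] = oldest
        self.movable_samples = np.flatnonzero(~np.isnan(self.lo_bound))

    @property
    def root_age(self) -> float:
        return float(self.ages[0])

    def child_max(self, i: int) -> float:
        a = self.ages[self.ch1[i]]
        j = self.ch2[i]
        return float(max(a, self.ages[j])) if j >= 0 else float(a)


class _BDSkyModel:
    """Array-based BDSKY likelihood with per-node terms."""

    name = "bdsky"

    def __init__(self, arrays: _TreeArrays, grid: TimeGrid, rho: float) -> None:
        self.a = arrays
        self.grid = grid
        self.rho = rho
        self.ws: FBDWorkspace | None = None
        if rho == 0.0 and np.any(arrays.ages[arrays.leaf_idx] == 0.0):
            raise ValidationError(
                "tree has a tip at the reference age but rho = 0; such an "
                "observation has probability zero"
            )

    def set_scalars(self, scalars: dict[str, float], origin: float) -> None:
        n = self.grid.n_bins
        params = BDSKYParams(
            origin_age=origin,
            lam=tuple(scalars[f"lambda_{i}"] for i in range(n)),
            mu=tuple(scalars[f"mu_{i}"] for i in range(n)),
            psi=tuple(scalars[f"psi_{i}"] for i in range(n)),
            rho=self.rho,
        )
        self.ws = FBDWorkspace(params, self.grid)
        self.origin = origin

    def node_term(self, i: int) -> float:
        """This node's additive contribution to the log-likelihood."""
        ws = self.ws
        age = float(self.a.ages[i])
        kind = self.a.kind[i]
        b = ws._bin_of(age)
        if kind == 2:
            return ws.log_q1(age) + math.log(ws.lam[b]) if ws.lam[b] > 0 else -math.inf
        if kind == 1:
            return math.log(ws.psi[b]) if ws.psi[b] > 0 else -math.inf
        if age == 0.0:
            return math.log(self.rho) if self.rho > 0 else -math.inf
        if ws.psi[b] <= 0:
            return -math.inf
        p = ws.p1(age)
        return -ws.log_q1(age) + math.log(ws.psi[b]) + (
            math.log(p) if p > 0 else -math.inf
        )

    def full_loglik(self) -> float:
        ws = self.ws
        a = self.a
        if self.origin <= a.root_age:
            return -math.inf
        p_or = ws.p(self.origin)
        if p_or >= 1.0:
            return -math.inf
        total = -math.log1p(-p_or) + ws.log_q(self.origin)
        with np.errstate(divide="ignore"):
            if a.bif_idx.size:
                x = a.ages[a.bif_idx]
                total += np.sum(ws.log_q(x))
                total += np.sum(np.log(ws.lam[self.grid.bin_of_internal(x)]))
            if a.sa_idx.size:
                z = a.ages[a.sa_idx]
                total += np.sum(np.log(ws.psi[self.grid.bin_of_internal(z)]))
            if a.leaf_idx.size:
                y = a.ages[a.leaf_idx]
                zero = y == 0.0
                if np.any(zero):
                    total += np.count_nonzero(zero) * math.log(self.rho)
                    y = y[~zero]
                if y.size:
                    total += -np.sum(ws.log_q(y))
                    total += np.sum(np.log(ws.psi[self.grid.bin_of_internal(y)]))
                    total += np.sum(np.log(ws.p(y)))
        return float(total) if not math.isnan(total) else -math.inf

    def origin_terms(self) -> float:
        ws = self.ws
        p_or = ws.p(self.origin)
        if p_or >= 1.0:
            return -math.inf
        return -math.log1p(-p_or) + ws.log_q(self.origin)


class _CoalModel:
    """Array-based piecewise-exponential coalescent likelihood."""

    name = "coalescent"

    def __init__(self, arrays: _TreeArrays, grid: TimeGrid, rho: float) -> None:
        if arrays.sa_idx.size:
            raise ValidationError(
                "the coalescent model requires a binary tree without "
                "sampled-ancestor nodes"
            )
        if arrays.leaf_idx.size < 2:
            raise ValidationError("coalescent likelihood needs at least 2 tips")
        self.a = arrays
        self.grid = grid
        self.traj: NTrajectory | None = None
        # +1 when a lineage is added (a tip, looking backward), -1 at a merge
        self.delta = np.where(arrays.kind == 0, 1, -1).astype(np.int64)

    def set_scalars(self, scalars: dict[str, float], origin=None) -> None:
        n = self.grid.n_bins
        params = CoalescentParams(
            growth=tuple(scalars[f"growth_{i}"] for i in range(n)),
            n_final=scalars["n_final"],
        )
        self.traj = NTrajectory(params, self.grid)

    def full_loglik(self) -> float:
        a = self.a
        traj = self.traj
        # sort by age, samples before coalescences at ties
        order = np.lexsort((-self.delta, a.ages))
        ages = a.ages[order]
        delta = self.delta[order]
        k = np.cumsum(delta)
        if k[-1] != 1 or np.any(k < 0):
            return -math.inf
        lam = traj.cumulative_intensity(ages)
        seg = np.diff(lam)
        kk = k[:-1]
        total = -np.sum(0.5 * kk * (kk - 1) * seg)
        total -= np.sum(traj.log_n(ages[delta < 0]))
        return float(total) if not math.isnan(total) else -math.inf


def _init_scalars(priors: PriorSpec, rng, attempt: int) -> dict[str, float]:
    out = {}
    for name, prior in priors.items():
        if name == "origin":
            continue
        out[name] = prior.median() if attempt == 0 else prior.sample(rng)
    return out


def run_mcmc(
    model: str,
    tree: TimeTree,
    grid: TimeGrid,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    rho: float = 0.0,
) -> Trace:
    """Sample the posterior of ``model`` ('bdsky' or 'coalescent') given
    a fixed-topology timetree.

    Fossil ages move only for samples with non-degenerate bounds in
    ``tree.tip_bounds``; all internal node ages move. Returns the full
    (unburned) trace together with per-move acceptance rates and the
    final post-burn-in ESS per scalar parameter. With
    ``config.prior_only`` the likelihood is constant and the chain
    samples the joint prior (used for prior-recovery validation).
    """
    if model not in ("bdsky", "coalescent"):
        raise ValidationError(f"unknown model {model!r}")
    config = config if config is not None else MCMCConfig()
    priors = priors if priors is not None else default_priors(model, grid)

    arrays = _TreeArrays(tree)
    lik = (_BDSkyModel if model == "bdsky" else _CoalModel)(arrays, grid, rho)
    prior_only = config.prior_only

    has_origin = model == "bdsky"
    if has_origin:
        cap = priors.require("origin").params["high"]
        if arrays.root_age >= cap:
            raise ValidationError(
                f"root age {arrays.root_age} exceeds the origin prior cap {cap}"
            )

    # -- initial state -------------------------------------------------
    init_rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    origin = None
    for attempt in range(1001):
        scalars = _init_scalars(priors, init_rng, attempt)
        if has_origin:
            root = arrays.root_age
            if tree.origin_age is not None and root < tree.origin_age < cap:
                origin = tree.origin_age
            else:
                origin = root + 0.25 * (cap - root)
        lik.set_scalars(scalars, origin)
        cur_lik = 0.0 if prior_only else lik.full_loglik()
        if math.isfinite(cur_lik):
            break
    else:
        raise RuntimeError(
            "could not find a starting state with finite posterior after 1000 "
            "prior draws; check that the tree, bounds and priors are consistent"
        )

    def origin_log_prior(orig: float, root: float) -> float:
        if not root < orig < cap:
            return -math.inf
        return -math.log(cap - root)

    scalar_names = list(scalars)
    lp_scalar = {name: priors[name].log_pdf(v) for name, v in scalars.items()}
    cur_prior = sum(lp_scalar.values())
    if has_origin:
        cur_prior += origin_log_prior(origin, arrays.root_age)
    if not math.isfinite(cur_prior):
        raise RuntimeError("initial state has zero prior density")

    positive = {
        name
        for name in scalar_names
        if priors[name].family in ("lognormal", "exponential", "gamma")
    }
    weights = dict(config.move_weights)
    if not has_origin:
        weights.pop("origin", None)
    if arrays.movable_samples.size == 0:
        weights.pop("tip_ages", None)
    if arrays.bif_idx.size == 0:
        weights.pop("node_ages", None)
    cats = [c for c in ("rates", "node_ages", "tip_ages", "origin") if c in weights]
    w = np.array([weights[c] for c in cats], dtype=float)
    if w.sum() <= 0:
        raise ValidationError("move weights sum to zero")
    cum_w = np.cumsum(w / w.sum())

    rng = np.random.default_rng(config.seed)
    n_prop = dict.fromkeys(cats, 0)
    n_acc = dict.fromkeys(cats, 0)
    scale_step = config.scale_step
    window_step = config.window_step
    n_adapt = 0
    ages = arrays.ages
    bif = arrays.bif_idx
    movable = arrays.movable_samples
    incremental = model == "bdsky" and not prior_only

    rows: list[dict] = []
    it = 0
    converged = False
    ess_final: dict[str, float] = {}
    sample_cols = [(int(i), f"age_{arrays.labels[i]}") for i in movable]

    def record() -> None:
        row = {
            "state": it,
            "posterior": cur_lik + cur_prior,
            "likelihood": cur_lik,
            "prior": cur_prior,
        }
        row.update(scalars)
        if has_origin:
            row["origin"] = origin
        row["root_age"] = arrays.root_age
        for i, col in sample_cols:
            row[col] = ages[i]
        rows.append(row)

    def age_move_delta_lik(i: int, new_age: float) -> float:
        """Log-likelihood change from moving one node's age."""
        nonlocal cur_lik
        if prior_only:
            ages[i] = new_age
            return 0.0
        if incremental:
            old_term = lik.node_term(i)
            old_age = ages[i]
            ages[i] = new_age
            new_term = lik.node_term(i)
            d = new_term - old_term
            if math.isnan(d):
                ages[i] = old_age
                return -math.inf if new_term == -math.inf else 0.0
            return d
        old_age = ages[i]
        ages[i] = new_age
        return lik.full_loglik() - cur_lik

    record()
    ess_names = scalar_names + (["origin"] if has_origin else [])

    for chunk in range(config.max_chunks):
        for _ in range(config.chain_length):
            it += 1
            cat = cats[int(np.searchsorted(cum_w, rng.random()))]
            n_prop[cat] += 1

            if cat == "rates":
                name = scalar_names[rng.integers(len(scalar_names))]
                old = scalars[name]
                if name in positive:
                    new, log_hr = scale_move(old, scale_step, rng)
                else:
                    new, log_hr = window_move(old, window_step, rng)
                lp_new = priors[name].log_pdf(new)
                accepted = False
                if lp_new > -math.inf:
                    scalars[name] = new
                    lik.set_scalars(scalars, origin)
                    new_lik = 0.0 if prior_only else lik.full_loglik()
                    delta = (new_lik - cur_lik) + (lp_new - lp_scalar[name]) + log_hr
                    if delta >= 0 or rng.random() < math.exp(delta):
                        cur_lik = new_lik
                        cur_prior += lp_new - lp_scalar[name]
                        lp_scalar[name] = lp_new
                        n_acc[cat] += 1
                        accepted = True
                    else:
                        scalars[name] = old
                        lik.set_scalars(scalars, origin)
                if config.adapt:
                    # diminishing adaptation toward the target acceptance
                    n_adapt += 1
                    gamma = 0.5 / (1.0 + n_adapt) ** 0.6
                    shift = gamma * ((1.0 if accepted else 0.0) - config.adapt_target)
                    if name in positive:
                        scale_step = min(max(scale_step * math.exp(shift), 1e-3), 5.0)
                    else:
                        window_step = min(max(window_step * math.exp(shift), 1e-3), 50.0)

            elif cat == "node_ages":
                i = int(bif[rng.integers(bif.size)])
                old_age = float(ages[i])
                lo = arrays.child_max(i)
                par = arrays.parent[i]
                if par >= 0:
                    hi = float(ages[par])
                elif has_origin:
                    hi = origin
                else:
                    hi = None
                if hi is None:  # root with no origin: reflected window
                    new_age = old_age + config.root_window * (2 * rng.random() - 1)
                    if new_age < lo:
                        new_age = 2 * lo - new_age
                    ok = True
                else:
                    ok = hi > lo
                    if ok:
                        new_age = lo + (hi - lo) * rng.random()
                if ok:
                    d_lik = age_move_delta_lik(i, new_age)
                    d_prior = 0.0
                    if has_origin and i == 0:
                        d_prior = origin_log_prior(origin, new_age) - origin_log_prior(
                            origin, old_age
                        )
                    delta = d_lik + d_prior
                    if delta >= 0 or rng.random() < math.exp(delta):
                        cur_lik += d_lik
                        cur_prior += d_prior
                        n_acc[cat] += 1
                    else:
                        ages[i] = old_age

            elif cat == "tip_ages":
                i = int(movable[rng.integers(movable.size)])
                lo = arrays.lo_bound[i]
                hi = arrays.hi_bound[i]
                if arrays.kind[i] == 1:  # sampled ancestor: above its child
                    lo = max(lo, float(ages[arrays.ch1[i]]))
                par = arrays.parent[i]
                if par >= 0:
                    hi = min(hi, float(ages[par]))
                elif has_origin:
                    hi = min(hi, origin)
                if hi > lo:
                    old_age = float(ages[i])
                    new_age = lo + (hi - lo) * rng.random()
                    d_lik = age_move_delta_lik(i, new_age)
                    if d_lik >= 0 or rng.random() < math.exp(d_lik):
                        cur_lik += d_lik
                        n_acc[cat] += 1
                    else:
                        ages[i] = old_age

            else:  # origin
                root = arrays.root_age
                old_origin = origin
                if rng.random() < 0.5:  # global redraw over the prior support
                    new_origin = root + (cap - root) * rng.random()
                else:  # local reflected window (symmetric; better mixing
                    # when the posterior hugs the root)
                    new_origin = old_origin + config.root_window * (
                        2.0 * rng.random() - 1.0
                    )
                    if new_origin < root:
                        new_origin = 2 * root - new_origin
                    if new_origin >= cap:
                        new_origin = old_origin  # reject out-of-support
                if prior_only:
                    origin = new_origin
                    lik.origin = new_origin
                    n_acc[cat] += 1
                else:
                    old_terms = lik.origin_terms()
                    lik.origin = new_origin
                    new_terms = lik.origin_terms()
                    d_lik = new_terms - old_terms
                    # uniform prior and proposal on the same interval cancel
                    if d_lik >= 0 or rng.random() < math.exp(d_lik):
                        origin = new_origin
                        cur_lik += d_lik
                        n_acc[cat] += 1
                    else:
                        lik.origin = old_origin

            if it % config.thin == 0:
                record()

        # re-anchor the running log-likelihood against float drift
        if not prior_only:
            cur_lik = lik.full_loglik()

        df = pd.DataFrame(rows)
        n_drop = int(np.ceil(config.burn_in * len(df)))
        kept = df.iloc[n_drop:]
        ess_final = {}
        ok_len = len(kept) >= 10
        for name in ess_names:
            try:
                ess_final[name] = _ess(kept[name].to_numpy()) if ok_len else 0.0
            except ValidationError:
                ess_final[name] = 0.0
        if ess_final and min(ess_final.values()) >= config.target_ess:
            converged = True
            break

    acceptance = {c: (n_acc[c] / n_prop[c] if n_prop[c] else 0.0) for c in cats}
    return Trace(
        records=pd.DataFrame(rows),
        model=model,
        scalar_names=scalar_names,
        acceptance=acceptance,
        ess=ess_final,
        converged=converged,
    )
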