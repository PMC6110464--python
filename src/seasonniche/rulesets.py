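"""Presence-only rule-set niche models fitted by a genetic algorithm.

A model is an ordered list of rules (climatic range boxes, negated boxes
and logistic rules), each predicting presence or absence; the first rule
matching an environmental vector wins and the default class is absence.
Rules are evolved by a genetic algorithm whose fitness is the significance
of a rule's accuracy gain over prior prevalence on an internal held-out
split.  An ensemble is formed best-subsets style: of R seeded replicates,
keep those with training omission below a cap, then retain the k replicates
whose commission (fraction of the modeling region predicted present) is
closest to the survivors' median commission.

This is a documented approximation in the spirit of classic genetic
rule-set algorithms; it makes no attempt to replicate any particular
implementation bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geodata import ClimateStack, EnvMatrix, GridSpec, OccurrenceSet, _resolve_months

PRESENCE, ABSENCE = 1, 0


@dataclass
class GAParams:
    population_size: int = 40
    max_generations: int = 25
    patience: int = 5
    elite_fraction: float = 0.25
    mutation_scale: float = 0.1      # fraction of the variable range
    internal_test_fraction: float = 0.3
    max_rules: int = 12
    background_size: int = 10_000


@dataclass
class Rule:
    """One atomic rule.  ``low``/``high`` bound a climatic box for the range
    kinds (unbounded variables use +-inf); ``coef``/``intercept`` define a
    logistic rule matching where sigmoid(x.coef + b) >= 0.5."""

    kind: str  # range | negated_range | logit
    predicted_class: int
    low: np.ndarray | None = None
    high: np.ndarray | None = None
    coef: np.ndarray | None = None
    intercept: float = 0.0
    fitness: float = -np.inf

    def __post_init__(self) -> None:
        if self.kind in ("range", "negated_range"):
            self.low = np.asarray(self.low, dtype=np.float64)
            self.high = np.asarray(self.high, dtype=np.float64)
            if (self.low > self.high).any():
                raise ValueError("rule interval low > high")
        elif self.kind == "logit":
            self.coef = np.asarray(self.coef, dtype=np.float64)
            if not np.isfinite(self.coef).all() or not np.isfinite(self.intercept):
                raise ValueError("logit coefficients must be finite")
        else:
            raise ValueError(f"unknown rule kind '{self.kind}'")

    def matches(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "range":
            return ((X >= self.low) & (X <= self.high)).all(axis=1)
        if self.kind == "negated_range":
            return ~((X >= self.low) & (X <= self.high)).all(axis=1)
        score = X @ self.coef + self.intercept
        return score >= 0.0

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "predicted_class": int(self.predicted_class),
                   "fitness": float(self.fitness)}
        if self.kind in ("range", "negated_range"):
            d["low"] = [None if not np.isfinite(v) else float(v) for v in self.low]
            d["high"] = [None if not np.isfinite(v) else float(v) for v in self.high]
        else:
            d["coef"] = [float(v) for v in self.coef]
            d["intercept"] = float(self.intercept)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        if d["kind"] in ("range", "negated_range"):
            low = [(-np.inf if v is None else v) for v in d["low"]]
            high = [(np.inf if v is None else v) for v in d["high"]]
            return cls(d["kind"], d["predicted_class"], low=low, high=high,
                       fitness=d.get("fitness", -np.inf))
        return cls(d["kind"], d["predicted_class"], coef=d["coef"],
                   intercept=d["intercept"], fitness=d.get("fitness", -np.inf))


@dataclass
class RuleSetModel:
    rules: list[Rule]
    omission: float
    commission: float
    seed: int
    columns: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """First matching rule wins; unmatched vectors default to absence."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.full(X.shape[0], ABSENCE, dtype=np.int8)
        unassigned = np.ones(X.shape[0], dtype=bool)
        for rule in self.rules:
            if not unassigned.any():
                break
            sel = rule.matches(X) & unassigned
            out[sel] = rule.predicted_class
            unassigned &= ~sel
        return out

    def to_dict(self) -> dict:
        return {
            "rules": [r.to_dict() for r in self.rules],
            "omission": float(self.omission),
            "commission": float(self.commission),
            "seed": int(self.seed),
            "columns": list(self.columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleSetModel":
        return cls(
            [Rule.from_dict(r) for r in d["rules"]],
            d["omission"], d["commission"], d["seed"], tuple(d["columns"]),
        )


@dataclass
class NicheEnsemble:
    """The k best rule-set models of a replicate run plus the full
    per-replicate omission/commission selection log."""

    members: list[RuleSetModel]
    selection_log: pd.DataFrame
    columns: tuple[str, ...]
    omission_max: float = 0.10

    @property
    def k(self) -> int:
        return len(self.members)

    def save(self, path: str | Path) -> Path:
        payload = {
            "omission_max": self.omission_max,
            "columns": list(self.columns),
            "members": [m.to_dict() for m in self.members],
            "selection_log": self.selection_log.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "NicheEnsemble":
        d = json.loads(Path(path).read_text())
        return cls(
            [RuleSetModel.from_dict(m) for m in d["members"]],
            pd.DataFrame(d["selection_log"]),
            tuple(d["columns"]),
            d["omission_max"],
        )


@dataclass
class SuitabilityMap:
    """Per-cell agreement (count of ensemble members predicting presence,
    NaN at nodata) and the consensus binary map."""

    grid: GridSpec
    agreement: np.ndarray
    k: int
    consensus: int

    def __post_init__(self) -> None:
        valid = self.agreement[~np.isnan(self.agreement)]
        if valid.size and valid.max() > self.k:
            raise ValueError("agreement exceeds ensemble size")

    @property
    def binary(self) -> np.ndarray:
        """True where agreement >= consensus; False elsewhere incl. nodata."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.agreement, nan=-1.0) >= self.consensus

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.agreement)


# ---------------------------------------------------------------------------
# Calibration split


def split_calibration(
    occ: OccurrenceSet, fraction: float = 0.8, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint calibration/evaluation partition with round(fraction*n)
    records used to calibrate."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(occ)
    if n < 5:
        raise ValueError("need at least 5 records to split")
    n_train = int(np.rint(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = set(perm[:n_train].tolist())
    train = [r for i, r in enumerate(occ.records) if i in train_idx]
    test = [r for i, r in enumerate(occ.records) if i not in train_idx]
    return (
        OccurrenceSet(train, provenance=f"{occ.provenance} [train]"),
        OccurrenceSet(test, provenance=f"{occ.provenance} [test]"),
    )


# ---------------------------------------------------------------------------
# Genetic algorithm


def _drop_constant_columns(
    presence: EnvMatrix, background: EnvMatrix
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    X = np.vstack([presence.values, background.values])
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(presence.columns, keep) if not k]
        warnings.warn(f"dropping constant variable(s): {dropped}", stacklevel=3)
    cols = tuple(c for c, k in zip(presence.columns, keep) if k)
    if not cols:
        raise ValueError("all variables constant; cannot fit")
    return presence.values[:, keep], background.values[:, keep], cols


def _random_rule(
    rng: np.random.Generator,
    Xp: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    scale: np.ndarray,
) -> Rule:
    p = Xp.shape[1]
    u = rng.random()
    if u < 0.6:  # range rule anchored on a presence point
        center = Xp[rng.integers(Xp.shape[0])]
        width = rng.random(p) * (hi - lo) * 0.5
        free = rng.random(p) < 0.2
        low = np.where(free, -np.inf, center - width)
        high = np.where(free, np.inf, center + width)
        return Rule("range", PRESENCE, low=low, high=high)
    if u < 0.75:  # negated box predicting absence outside a climatic core
        center = Xp[rng.integers(Xp.shape[0])]
        width = (0.5 + rng.random(p)) * (hi - lo) * 0.5
        return Rule("negated_range", ABSENCE, low=center - width, high=center + width)
    coef = rng.standard_normal(p) / np.where(scale > 0, scale, 1.0)
    x0 = Xp[rng.integers(Xp.shape[0])]
    return Rule("logit", PRESENCE, coef=coef, intercept=-float(x0 @ coef))


def _seed_rules(Xp: np.ndarray) -> list[Rule]:
    """Data-informed initial rules: presence-quantile climatic boxes."""
    rules = []
    for q in (0.0, 0.01, 0.025, 0.05, 0.10):
        low = np.quantile(Xp, q, axis=0)
        high = np.quantile(Xp, 1 - q, axis=0)
        rules.append(Rule("range", PRESENCE, low=low, high=high))
    return rules


def _rule_fitness(rule: Rule, X: np.ndarray, y: np.ndarray) -> float:
    """Significance (z-score) of the rule's accuracy gain over prior
    prevalence among the points it matches."""
    m = rule.matches(X)
    n_m = int(m.sum())
    if n_m == 0:
        return -np.inf
    prior = float((y == rule.predicted_class).mean())
    prior = min(max(prior, 1e-9), 1 - 1e-9)
    acc = float((y[m] == rule.predicted_class).mean())
    z = (acc - prior) * np.sqrt(n_m) / np.sqrt(prior * (1 - prior))
    return float(z)


def _mutate(rule: Rule, rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray,
            scale: np.ndarray, mutation_scale: float) -> Rule:
    if rule.kind in ("range", "negated_range"):
        low, high = rule.low.copy(), rule.high.copy()
        p = low.size
        j = rng.integers(p)
        action = rng.random()
        step = mutation_scale * (hi[j] - lo[j])
        if action < 0.4:  # point mutation of a bound
            if rng.random() < 0.5 and np.isfinite(low[j]):
                low[j] += rng.normal(0, step)
            elif np.isfinite(high[j]):
                high[j] += rng.normal(0, step)
        elif action < 0.6:  # deletion: free a variable
            low[j], high[j] = -np.inf, np.inf
        else:  # insertion: re-constrain a variable around its box midpoint
            mid = (lo[j] + hi[j]) / 2 if not np.isfinite(low[j]) else (low[j] + high[j]) / 2
            w = (0.25 + rng.random()) * (hi[j] - lo[j]) * 0.5
            low[j], high[j] = mid - w, mid + w
        low, high = np.minimum(low, high), np.maximum(low, high)
        return Rule(rule.kind, rule.predicted_class, low=low, high=high)
    coef = rule.coef.copy()
    j = rng.integers(coef.size)
    coef[j] += rng.normal(0, mutation_scale) / (scale[j] if scale[j] > 0 else 1.0)
    intercept = rule.intercept + rng.normal(0, mutation_scale)
    return Rule("logit", rule.predicted_class, coef=coef, intercept=intercept)


def _crossover(a: Rule, b: Rule, rng: np.random.Generator) -> Rule:
    if a.kind in ("range", "negated_range") and b.kind in ("range", "negated_range"):
        take = rng.random(a.low.size) < 0.5
        low = np.where(take, a.low, b.low)
        high = np.where(take, a.high, b.high)
        low, high = np.minimum(low, high), np.maximum(low, high)
        return Rule(a.kind, a.predicted_class, low=low, high=high)
    if a.kind == "logit" and b.kind == "logit":
        take = rng.random(a.coef.size) < 0.5
        coef = np.where(take, a.coef, b.coef)
        return Rule("logit", a.predicted_class, coef=coef,
                    intercept=float((a.intercept + b.intercept) / 2))
    return a


def fit_rule_model(
    presence: EnvMatrix,
    background: EnvMatrix,
    ga_params: GAParams | None = None,
    seed: int = 0,
) -> RuleSetModel:
    """Evolve a rule-set model from presence points and background cells.

    Reproducible under ``seed``.  Constant variables are dropped with a
    warning.  The returned model records training omission (fraction of
    presence points predicted absent) and commission (fraction of
    background cells predicted present).
    """
    params = ga_params or GAParams()
    if presence.n < 5:
        raise ValueError("need at least 5 presence records")
    Xp, Xb, cols = _drop_constant_columns(presence, background)
    rng = np.random.default_rng(seed)

    X = np.vstack([Xp, Xb])
    y = np.concatenate([
        np.full(Xp.shape[0], PRESENCE, dtype=np.int8),
        np.full(Xb.shape[0], ABSENCE, dtype=np.int8),
    ])
    # internal split for rule fitness (held out from rule construction);
    # presence and background are balanced 50:50 in the evaluation sample so
    # prevalence does not reward indiscriminately wide rules
    eval_p = rng.random(Xp.shape[0]) < params.internal_test_fraction
    if eval_p.sum() < 2:
        eval_p[:] = True
    n_bal = max(int(eval_p.sum()), 2)
    bg_eval = rng.choice(Xb.shape[0], size=min(max(n_bal * 1, 50), Xb.shape[0]),
                         replace=False)
    Xe = np.vstack([Xp[eval_p], Xb[bg_eval]])
    ye = np.concatenate([
        np.full(int(eval_p.sum()), PRESENCE, dtype=np.int8),
        np.full(bg_eval.size, ABSENCE, dtype=np.int8),
    ])
    Xp_train = Xp[~eval_p]
    if Xp_train.shape[0] < 2:
        Xp_train = Xp

    lo, hi = X.min(axis=0), X.max(axis=0)
    scale = X.std(axis=0)

    population = _seed_rules(Xp_train)
    while len(population) < params.population_size:
        population.append(_random_rule(rng, Xp_train, lo, hi, scale))
    for rule in population:
        rule.fitness = _rule_fitness(rule, Xe, ye)

    best = max(r.fitness for r in population)
    stagnant = 0
    n_elite = max(int(params.elite_fraction * params.population_size), 2)
    for _gen in range(params.max_generations):
        population.sort(key=lambda r: r.fitness, reverse=True)
        parents = population[:n_elite]
        children: list[Rule] = list(parents)
        while len(children) < params.population_size:
            u = rng.random()
            if u < 0.5:
                child = _mutate(parents[rng.integers(n_elite)], rng, lo, hi,
                                scale, params.mutation_scale)
            elif u < 0.8:
                a, b = rng.integers(n_elite, size=2)
                child = _crossover(parents[a], parents[b], rng)
            else:
                child = _random_rule(rng, Xp_train, lo, hi, scale)
            children.append(child)
        for rule in children[n_elite:]:
            rule.fitness = _rule_fitness(rule, Xe, ye)
        population = children
        new_best = max(r.fitness for r in population)
        if new_best > best + 1e-12:
            best, stagnant = new_best, 0
        else:
            stagnant += 1
            if stagnant >= params.patience:
                break

    # final model: forward selection in fitness order — a rule enters only
    # if the points it newly claims improve balanced accuracy on the
    # held-out split (default class is absence, so presence rules must
    # capture more presence mass than background mass)
    population.sort(key=lambda r: r.fitness, reverse=True)
    rules: list[Rule] = []
    assigned = np.zeros(Xe.shape[0], dtype=bool)
    n_pe = max(int((ye == PRESENCE).sum()), 1)
    n_be = max(int((ye == ABSENCE).sum()), 1)
    for rule in population:
        if len(rules) >= params.max_rules:
            break
        if not np.isfinite(rule.fitness):
            continue
        m = rule.matches(Xe) & ~assigned
        if not m.any():
            continue  # redundant: adds nothing to the decision
        pres_frac = float((ye[m] == PRESENCE).sum()) / n_pe
        bg_frac = float((ye[m] == ABSENCE).sum()) / n_be
        gain = (pres_frac - bg_frac if rule.predicted_class == PRESENCE
                else bg_frac - pres_frac)
        if gain <= 0:
            continue
        rules.append(rule)
        assigned |= m
    if not rules:
        rules = _seed_rules(Xp)[:1]

    model = RuleSetModel(rules, omission=0.0, commission=0.0, seed=seed, columns=cols)
    pred_p = model.predict(Xp)
    pred_b = model.predict(Xb)
    model.omission = float((pred_p == ABSENCE).mean())
    model.commission = float((pred_b == PRESENCE).mean())
    return model


def select_best_subset(
    replicates: Sequence[RuleSetModel],
    region_cells: EnvMatrix,
    omission_max: float = 0.10,
    k: int = 10,
) -> NicheEnsemble:
    """Best-subsets selection: filter replicates to training omission <=
    ``omission_max``, then keep the ``k`` whose commission over the region
    cells is closest to the survivors' median commission (ties broken by
    lower omission, then replicate index)."""
    log_rows = []
    survivors: list[tuple[int, RuleSetModel, float]] = []
    cols = replicates[0].columns
    col_idx = [region_cells.columns.index(c) for c in cols]
    Xr = region_cells.values[:, col_idx]
    for i, model in enumerate(replicates):
        commission = float((model.predict(Xr) == PRESENCE).mean())
        passed = model.omission <= omission_max
        log_rows.append({
            "replicate": i, "omission": model.omission,
            "commission": commission, "passed_omission": passed,
        })
        if passed:
            survivors.append((i, model, commission))
    log = pd.DataFrame(log_rows)
    if len(survivors) < k:
        raise ValueError(
            f"only {len(survivors)} of {len(replicates)} replicates passed the "
            f"omission filter (<= {omission_max}); need {k}"
        )
    med = float(np.median([c for _, _, c in survivors]))
    ranked = sorted(survivors, key=lambda t: (abs(t[2] - med), t[1].omission, t[0]))
    members = [m for _, m, _ in ranked[:k]]
    selected = {id(m) for m in members}
    log["selected"] = [id(r) in selected for r in replicates]
    return NicheEnsemble(members, log, cols, omission_max)


def predict(
    ensemble: NicheEnsemble,
    stack: ClimateStack,
    months: int | str | Sequence[int],
    consensus: int | None = None,
) -> SuitabilityMap:
    """Project the ensemble onto the season-mean climate of ``months``.

    Agreement counts members predicting presence per cell; the binary map
    thresholds agreement at ``consensus`` (default: majority, ceil(k/2)).
    Projecting onto other months' layers is the same call — that is what
    transferability means here.
    """
    months = _resolve_months(months)
    env = stack.env_grid(months)
    grid = stack.grid
    flat = env.reshape(-1, env.shape[-1])
    valid = ~np.isnan(flat).any(axis=1)
    from .geodata import VARIABLES

    col_idx = [VARIABLES.index(c) for c in ensemble.columns]
    X = flat[valid][:, col_idx]
    agreement = np.full(flat.shape[0], np.nan)
    votes = np.zeros(X.shape[0])
    for member in ensemble.members:
        votes += member.predict(X) == PRESENCE
    agreement[valid] = votes
    k = ensemble.k
    consensus = int(np.ceil(k / 2)) if consensus is None else consensus
    return SuitabilityMap(grid, agreement.reshape(grid.shape), k, consensus)


def geographic_overlap(map_a: SuitabilityMap, map_b: SuitabilityMap) -> dict:
    """Directional percent overlap of two binary suitability maps.

    overlap(a->b) = 100 * |a AND b| / |a| over cells valid in both maps;
    ``None`` (printed NA) where the source map predicts no area.
    """
    if not map_a.grid.approx_equal(map_b.grid):
        raise ValueError("maps must share one grid")
    valid = map_a.valid_mask & map_b.valid_mask
    a = map_a.binary & valid
    b = map_b.binary & valid
    inter = int((a & b).sum())
    na, nb = int(a.sum()), int(b.sum())
    return {
        "a_to_b": (100.0 * inter / na) if na else None,
        "b_to_a": (100.0 * inter / nb) if nb else None,
        "cells_a": na,
        "cells_b": nb,
        "cells_intersection": inter,
    }
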