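"""Covariation-induced deviation of activity (CODA).

The null model of a double mutant's activity is mutation independence: its
relative activity is a smooth function of the two single-mutant activities,
learned by support-vector regression (RBF kernel) on *all* observed double
mutants — functional and nonfunctional alike, with no knowledge of any
structure.  A double mutant whose observed activity exceeds this prediction
(a compensatory rescue) is the covariation signal of a base pair.

Score per double mutant:

    CODA = (RA_obs - RA_pred) / (RA_pred + shift)

The CODA distribution over all double mutants is a mixture of a dominant
near-zero component (unpaired positions) and a sparse high-mean component
(paired positions).  The mixture is de-mixed empirically: component 1 from
all scores, component 2 from the outliers beyond ``a1 + k_sd * sd1``, and
the prior P(paired) from the outlier fraction.  The pairing score is the
log-Bayes score of the paired component under a two-state naive Bayes
classifier:

    Ps = ln p(CODA | paired) / p(CODA)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.svm import SVR

from .library import ActivityTable, Sub, SubKey

logger = logging.getLogger(__name__)

MIN_DOUBLES = 50


@dataclass
class IndependentMutationModel:
    """RBF-kernel SVR mapping two single-mutant RAs to the double-mutant RA.

    Training pairs are duplicated with swapped argument order and prediction
    averages the two orderings, so the fitted surface is symmetric.
    """

    C: float
    gamma: float
    _svr: SVR
    n_training_doubles: int

    def predict(self, ra_i: np.ndarray, ra_j: np.ndarray) -> np.ndarray:
        ra_i = np.asarray(ra_i, dtype=float)
        ra_j = np.asarray(ra_j, dtype=float)
        fwd = self._svr.predict(np.column_stack([ra_i, ra_j]))
        rev = self._svr.predict(np.column_stack([ra_j, ra_i]))
        return np.maximum(0.5 * (fwd + rev), 0.0)


def fit_independent_model(
    table: ActivityTable,
    C: float = 2000.0,
    gamma: float = 2.0,
    epsilon: float = 0.01,
    max_train: int | None = 2000,
    seed: int = 0,
) -> IndependentMutationModel:
    """Fit the independent-mutation SVR on every double entry of ``table``.

    Doubles missing a constituent single are skipped with a warning.  When
    the table holds more than ``max_train`` usable doubles, a seeded random
    subsample of that size is used (libsvm training is quadratic in n; the
    two-feature response surface is smooth and needs no more support).
    """
    X, y = [], []
    n_skipped = 0
    for (si, sj), rec in table.doubles.items():
        ri = table.singles.get(si)
        rj = table.singles.get(sj)
        if ri is None or rj is None:
            n_skipped += 1
            continue
        X.append((ri.ra, rj.ra))
        y.append(rec.ra)
    if n_skipped:
        logger.warning("skipped %d doubles missing a constituent single", n_skipped)
    if len(y) < MIN_DOUBLES:
        raise ValueError(
            f"only {len(y)} usable double mutants; need at least {MIN_DOUBLES}"
        )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if max_train is not None and len(y) > max_train:
        idx = np.random.default_rng(seed).choice(len(y), size=max_train, replace=False)
        X, y = X[idx], y[idx]
    # duplicate with swapped order: the model has no argument asymmetry
    X_sym = np.vstack([X, X[:, ::-1]])
    y_sym = np.concatenate([y, y])
    svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon, cache_size=500)
    svr.fit(X_sym, y_sym)
    return IndependentMutationModel(C=C, gamma=gamma, _svr=svr, n_training_doubles=len(y))


def predict_double(model: IndependentMutationModel, ra_i: float, ra_j: float) -> float:
    """Predicted double-mutant RA under mutation independence (symmetric)."""
    if ra_i < 0 or ra_j < 0:
        raise ValueError("single-mutant activities must be nonnegative")
    return float(model.predict(np.array([ra_i]), np.array([ra_j]))[0])


def coda_score(ra_obs: float, ra_pred: float, shift: float = 0.2) -> float:
    """Deviation of observed from predicted RA, on a relative scale.

    The shift keeps the denominator away from zero where predicted
    activities are small; results are robust for shift in [0.1, 0.5].
    """
    if ra_pred < 0:
        raise ValueError("predicted activity must be nonnegative")
    return (ra_obs - ra_pred) / (ra_pred + shift)


@dataclass(frozen=True)
class MixtureModel:
    """Two-Gaussian description of the CODA score distribution.

    Component 1 (``a1``, ``sd1``): unpaired positions, the bulk.
    Component 2 (``a2``, ``sd2``): paired positions, estimated from scores
    beyond ``a1 + k_sd * sd1``.  ``p_paired`` is the outlier fraction.
    """

    a1: float
    sd1: float
    a2: float
    sd2: float
    p_paired: float
    k_sd: float = 3.0

    def __post_init__(self):
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("component standard deviations must be positive")
        if not 0 <= self.p_paired < 1:
            raise ValueError("p_paired must lie in [0, 1)")


def fit_mixture(coda_scores: Iterable[float], k_sd: float = 3.0) -> MixtureModel:
    """Empirical de-mixing of the CODA score distribution.

    The bulk statistics (a1, sd1) come from all scores — the paired
    component is too sparse to perturb them.  The paired component's
    statistics come from the outlier subset beyond ``a1 + k_sd*sd1``, whose
    relative size is the prior P(paired).
    """
    x = np.asarray(list(coda_scores), dtype=float)
    if len(x) < 100:
        raise ValueError(f"need at least 100 CODA scores, got {len(x)}")
    a1 = float(np.mean(x))
    sd1 = float(np.std(x, ddof=1))
    if sd1 == 0:
        raise ValueError("degenerate CODA scores: zero variance")
    subset = x[x > a1 + k_sd * sd1]
    if len(subset) < 2:
        raise ValueError("no covariation signal detected")
    a2 = float(np.mean(subset))
    sd2 = float(np.std(subset, ddof=1))
    if sd2 == 0:
        sd2 = sd1  # outliers numerically identical; fall back to bulk width
    p_paired = len(subset) / len(x)
    return MixtureModel(a1=a1, sd1=sd1, a2=a2, sd2=sd2, p_paired=p_paired, k_sd=k_sd)


def pairing_score(coda: float | np.ndarray, mixture: MixtureModel) -> float | np.ndarray:
    """Naive-Bayes log score that a CODA value arose from the paired component.

    Ps = ln[ p(CODA|paired) / p(CODA) ] with
    p(CODA) = p(CODA|paired) P(paired) + p(CODA|unpaired) (1 - P(paired)).
    """
    coda = np.asarray(coda, dtype=float)
    lp_pair = norm.logpdf(coda, mixture.a2, mixture.sd2)
    lp_unpair = norm.logpdf(coda, mixture.a1, mixture.sd1)
    p = mixture.p_paired
    # log-sum-exp for the marginal density
    m = np.maximum(lp_pair, lp_unpair)
    log_marginal = m + np.log(
        p * np.exp(lp_pair - m) + (1.0 - p) * np.exp(lp_unpair - m)
    )
    out = lp_pair - log_marginal
    return float(out) if out.ndim == 0 else out


@dataclass
class MutationScore:
    """Per-double-mutation CODA and pairing score with its context."""

    key: SubKey
    ra_obs: float
    ra_pred: float
    coda: float
    ps: float


@dataclass
class PairScoreMap:
    """CODA output: scores per double mutation and per position pair."""

    per_mutation: dict[SubKey, MutationScore]
    per_position: dict[tuple[int, int], float]
    n_mutants: dict[tuple[int, int], int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "i": s.key[0][0],
                "j": s.key[1][0],
                "alt_i": s.key[0][1],
                "alt_j": s.key[1][1],
                "ra_obs": s.ra_obs,
                "ra_pred": s.ra_pred,
                "coda": s.coda,
                "ps": s.ps,
            }
            for s in self.per_mutation.values()
        ]
        return pd.DataFrame(
            rows, columns=["i", "j", "alt_i", "alt_j", "ra_obs", "ra_pred", "coda", "ps"]
        )

    def position_frame(self) -> pd.DataFrame:
        rows = [
            {"i": i, "j": j, "ps_max": ps, "n_mutants": self.n_mutants.get((i, j), 0)}
            for (i, j), ps in sorted(self.per_position.items())
        ]
        return pd.DataFrame(rows, columns=["i", "j", "ps_max", "n_mutants"])

    def to_tsv(self, mutation_path: str | Path, position_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(mutation_path, sep="\t", index=False)
        if position_path is not None:
            self.position_frame().to_csv(position_path, sep="\t", index=False)

    @classmethod
    def from_position_tsv(cls, path: str | Path) -> "PairScoreMap":
        df = pd.read_csv(path, sep="\t")
        per_position = {
            (int(r["i"]), int(r["j"])): float(r["ps_max"]) for _, r in df.iterrows()
        }
        n_mutants = {
            (int(r["i"]), int(r["j"])): int(r.get("n_mutants", 0)) for _, r in df.iterrows()
        }
        return cls(per_mutation={}, per_position=per_position, n_mutants=n_mutants)


def score_all(
    table: ActivityTable,
    model: IndependentMutationModel,
    mixture: MixtureModel,
    shift: float = 0.2,
    aggregate: Literal["max", "mean"] = "max",
) -> PairScoreMap:
    """CODA and pairing scores for every double entry, plus a per-position
    aggregate (default: max over the up-to-9 mutation combinations)."""
    keys, ra_i, ra_j, ra_obs = [], [], [], []
    for (si, sj), rec in table.doubles.items():
        ri = table.singles.get(si)
        rj = table.singles.get(sj)
        if ri is None or rj is None:
            continue
        keys.append((si, sj))
        ra_i.append(ri.ra)
        ra_j.append(rj.ra)
        ra_obs.append(rec.ra)
    ra_pred = model.predict(np.asarray(ra_i), np.asarray(ra_j))
    ra_obs = np.asarray(ra_obs)
    coda = (ra_obs - ra_pred) / (ra_pred + shift)
    ps = pairing_score(coda, mixture)

    per_mutation: dict[SubKey, MutationScore] = {}
    per_position: dict[tuple[int, int], float] = {}
    per_position_all: dict[tuple[int, int], list[float]] = {}
    for k, (key, o, pr, c, s) in enumerate(zip(keys, ra_obs, ra_pred, coda, ps)):
        per_mutation[key] = MutationScore(
            key=key, ra_obs=float(o), ra_pred=float(pr), coda=float(c), ps=float(s)
        )
        pos = (key[0][0], key[1][0])
        per_position_all.setdefault(pos, []).append(float(s))
    for pos, values in per_position_all.items():
        per_position[pos] = max(values) if aggregate == "max" else float(np.mean(values))
    n_mutants = {pos: len(v) for pos, v in per_position_all.items()}
    return PairScoreMap(
        per_mutation=per_mutation, per_position=per_position, n_mutants=n_mutants
    )


def compute_coda_scores(
    table: ActivityTable, model: IndependentMutationModel, shift: float = 0.2
) -> np.ndarray:
    """CODA scores of all usable doubles (the mixture-fitting input)."""
    ra_i, ra_j, ra_obs = [], [], []
    for (si, sj), rec in table.doubles.items():
        ri = table.singles.get(si)
        rj = table.singles.get(sj)
        if ri is None or rj is None:
            continue
        ra_i.append(ri.ra)
        ra_j.append(rj.ra)
        ra_obs.append(rec.ra)
    ra_pred = model.predict(np.asarray(ra_i), np.asarray(ra_j))
    return (np.asarray(ra_obs) - ra_pred) / (ra_pred + shift)


def run_coda(
    table: ActivityTable,
    C: float = 2000.0,
    gamma: float = 2.0,
    shift: float = 0.2,
    k_sd: float = 3.0,
    epsilon: float = 0.01,
    max_train: int | None = 2000,
    seed: int = 0,
    aggregate: Literal["max", "mean"] = "max",
) -> tuple[IndependentMutationModel, MixtureModel, PairScoreMap]:
    """Fit the independent model and mixture, then score every double."""
    model = fit_independent_model(
        table, C=C, gamma=gamma, epsilon=epsilon, max_train=max_train, seed=seed
    )
    scores = compute_coda_scores(table, model, shift=shift)
    mixture = fit_mixture(scores, k_sd=k_sd)
    score_map = score_all(table, model, mixture, shift=shift, aggregate=aggregate)
    return model, mixture, score_map
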