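"""Boltzmann-weighted aggregation of per-state docking scores.

Docking a compound against a single structure ignores conformational
heterogeneity; docking it against every state of an ensemble produces one
score per state.  Boltzmann docking collapses those into a single number
by averaging the per-state scores weighted by the states' equilibrium
probabilities π_i:

    S_boltzmann = Σ_i π_i · s_i / Σ_i π_i

with the sum restricted to states where the compound was actually scored
(missing entries drop out and the weights renormalize over the rest).
The pose generation itself is external — any docking engine's score
matrix can be consumed, with the score polarity declared in the file.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError

logger = logging.getLogger(__name__)


class UnscoredCompound(ContractError):
    """A compound has no non-missing score in any state."""


@dataclass
class ScoreMatrix:
    """Per-compound, per-state docking scores.

    ``scores`` is a (n_compounds, n_states) float DataFrame indexed by
    compound_id with state_id columns; NaN marks a missing docking.
    ``higher_better`` records the engine's score polarity.
    """

    scores: pd.DataFrame
    higher_better: bool = True

    def __post_init__(self) -> None:
        if self.scores.shape[1] < 1:
            raise ContractError("score matrix needs at least one state column")
        if self.scores.index.duplicated().any() or self.scores.columns.duplicated().any():
            raise ContractError("duplicate compound_ids or state_ids in score matrix")

    @property
    def compounds(self) -> list[str]:
        return list(self.scores.index)

    @property
    def states(self) -> list[str]:
        return list(self.scores.columns)


def read_score_matrix(path: str | Path) -> ScoreMatrix:
    """Read a CSV score matrix (first column compound_id, one column per state).

    A leading comment line ``# polarity=lower_better`` flips the score
    polarity; empty cells are missing dockings.
    """
    path = Path(path)
    higher_better = True
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "polarity=lower_better" in first.replace(" ", ""):
                higher_better = False
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(io.StringIO(body), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ScoreMatrix(scores=df.astype(float), higher_better=higher_better)


def write_score_matrix(matrix: ScoreMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# polarity={'higher_better' if matrix.higher_better else 'lower_better'}\n"
        )
        out = matrix.scores.copy()
        out.index.name = "compound_id"
        out.to_csv(fh)


def boltzmann_score(
    scores: Sequence[float], populations: Sequence[float]
) -> float:
    """Population-weighted average docking score over scored states.

    Missing scores (NaN) are skipped and the weights renormalized over the
    remaining states, so the result is always bracketed by the per-state
    extremes and invariant to rescaling all populations by a constant.
    """
    s = np.asarray(scores, dtype=float)
    w = np.asarray(populations, dtype=float)
    if s.shape != w.shape:
        raise ContractError("scores and populations must be aligned")
    if np.any(w < 0):
        raise ContractError("populations must be non-negative")
    mask = ~np.isnan(s)
    if not mask.any():
        raise UnscoredCompound("all scores missing")
    wsum = w[mask].sum()
    if wsum <= 0:
        raise ContractError("degenerate weights: zero total population over scored states")
    return float(np.dot(w[mask], s[mask]) / wsum)


@dataclass
class RankedList:
    """Ranked compounds with their Boltzmann scores and state coverage."""

    table: pd.DataFrame  # columns: compound_id, boltzmann_score, coverage, rank
    excluded: list[str] = field(default_factory=list)  # low-coverage compound_ids

    def top(self, n: int) -> pd.DataFrame:
        return self.table.head(n)


def rank_compounds(
    matrix: ScoreMatrix,
    populations: Mapping[str, float],
    top_n: int | None = None,
    min_coverage: float = 0.0,
) -> RankedList:
    """Rank compounds by Boltzmann-weighted score, best first.

    ``coverage`` is the fraction of states in which a compound was scored;
    compounds below ``min_coverage`` (and fully unscored ones) are dropped
    into the exclusion log rather than ranked on thin evidence.  Ties are
    broken by compound_id.  With a single state this reduces to ranking by
    the raw score — the crystal-structure screening limit.
    """
    if top_n is not None and top_n < 1:
        raise ConfigError("top_n must be >= 1")
    missing = set(matrix.states) - set(populations)
    if missing:
        raise ConfigError(f"populations missing for states: {sorted(missing)}")

    w = np.array([populations[s] for s in matrix.states], dtype=float)
    rows = []
    excluded: list[str] = []
    for cid, s in matrix.scores.iterrows():
        vals = s.to_numpy(dtype=float)
        cov = float(np.mean(~np.isnan(vals)))
        if cov == 0.0 or cov < min_coverage:
            excluded.append(str(cid))
            continue
        rows.append((str(cid), boltzmann_score(vals, w), cov))
    if excluded:
        logger.info("excluded %d compounds below coverage %.2f: %s",
                    len(excluded), min_coverage, excluded)

    sign = -1.0 if matrix.higher_better else 1.0
    rows.sort(key=lambda r: (sign * r[1], r[0]))
    df = pd.DataFrame(rows, columns=["compound_id", "boltzmann_score", "coverage"])
    df["rank"] = np.arange(1, len(df) + 1)
    if top_n is not None:
        df = df.head(top_n)
    return RankedList(table=df, excluded=excluded)
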