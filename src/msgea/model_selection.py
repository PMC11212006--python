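"""Variable-set construction and stepwise forward selection.

Eight candidate predictor sets are compared: the six single-resolution
sets (all nine variable types at one grain size, plus elevation at the
base resolution), the all-resolution set, and a forward-selected subset of
the latter.  Forward selection follows the double stopping rule of
Blanchet-style selection against a significant global model: a candidate
enters only while its marginal permutation p-value stays below alpha, its
adjusted-R^2 gain is positive, and the growing model's adjusted R^2 does
not exceed the global model's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ordination
from .terrain import (
    DEFAULT_RESOLUTIONS,
    VARIABLE_TYPES,
    EnvironmentMatrix,
    column_name,
    parse_column,
)

logger = logging.getLogger("msgea")


class SelectionError(RuntimeError):
    pass


@dataclass
class VariableSet:
    """A named, ordered predictor column list.

    ``provenance`` is non-empty only for forward-selected sets: one row
    per selection step with the running adjusted R^2 and the marginal
    permutation p-value.
    """

    name: str
    columns: list[str]
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["step", "column", "adj_r2", "p"])
    )

    def __len__(self) -> int:
        return len(self.columns)


def build_variable_sets(
    env: EnvironmentMatrix,
    resolutions=DEFAULT_RESOLUTIONS,
    base_resolution: float = 0.5,
) -> list[VariableSet]:
    """The six single-resolution sets plus the all-resolution set.

    Every set includes elevation at the base resolution; each
    single-resolution set therefore has 10 columns and the full set
    9 types x 6 resolutions + 1 = 55.
    """
    elev = column_name("ELEV", base_resolution)
    missing = []
    sets = []
    for res in resolutions:
        cols = [column_name(t, res) for t in VARIABLE_TYPES] + [elev]
        missing += [c for c in cols if c not in env.data.columns]
        sets.append(VariableSet(name=f"VS-{res:g}m", columns=cols))
    all_cols = [
        column_name(t, r) for t in VARIABLE_TYPES for r in resolutions
    ] + [elev]
    sets.append(VariableSet(name="VS-all", columns=all_cols))
    if missing:
        raise ordination.ModelError(
            f"environment matrix lacks required columns: {sorted(set(missing))[:6]}"
        )
    return sets


def _candidate_order(columns) -> list[str]:
    """Deterministic tie-break order: variable-type order, then resolution."""
    def key(c):
        vtype, res = parse_column(c)
        t = VARIABLE_TYPES.index(vtype) if vtype in VARIABLE_TYPES else -1
        return (t, res)

    return sorted(columns, key=key)


def forward_select(
    Y,
    candidates: EnvironmentMatrix,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    max_steps: int | None = None,
) -> VariableSet:
    """Stepwise forward selection of predictor columns against Y.

    The global model over all candidates must first be significant at
    ``alpha`` by permutation test, else selection is refused.  Each step
    evaluates every remaining candidate's adjusted-R^2 gain; the best
    candidate enters if its marginal permutation p (partial RDA conditioned
    on the already-selected columns) is below ``alpha``, its gain is
    positive, and the new adjusted R^2 does not exceed the global model's.
    Deterministic given ``seed``; ties break by canonical column order.
    """
    df = candidates.data
    Ya = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    # the scope model tolerates collinear candidate pools (rank basis used)
    global_model = ordination.rda(Ya, df, allow_deficient=True)
    p_global, _ = ordination.permutation_test(Ya, df, n_perm=n_perm, seed=seed)
    if p_global >= alpha:
        raise SelectionError(
            f"global model not significant (p={p_global:.4f} >= {alpha}); "
            "forward selection refused"
        )
    global_adj = global_model.adj_r2
    logger.info("forward_select: global adjR2=%.4f (p=%.4g)", global_adj, p_global)

    remaining = _candidate_order(df.columns)
    selected: list[str] = []
    trace = []
    current_adj = 0.0  # intercept-only null model
    step = 0
    while remaining:
        if max_steps is not None and step >= max_steps:
            break
        gains = []
        for col in remaining:
            try:
                m = ordination.rda(Ya, df[selected + [col]])
            except ordination.ModelError:
                continue  # candidate collinear with the selected set
            gains.append((m.adj_r2 - current_adj, col, m.adj_r2))
        if not gains:
            break
        best_gain, best_col, best_adj = max(gains, key=lambda g: g[0])
        if best_gain <= 0 or best_adj > global_adj:
            break
        p_marg, _ = ordination.permutation_test(
            Ya,
            df[[best_col]],
            Z=df[selected] if selected else None,
            n_perm=n_perm,
            seed=seed + step + 1,
        )
        if p_marg >= alpha:
            break
        selected.append(best_col)
        remaining.remove(best_col)
        step += 1
        trace.append({"step": step, "column": best_col, "adj_r2": best_adj, "p": p_marg})
        logger.info("forward_select step %d: +%s (adjR2=%.4f, p=%.4g)", step, best_col, best_adj, p_marg)
        current_adj = best_adj
    return VariableSet(
        name="VS-fwd", columns=selected, provenance=pd.DataFrame(trace)
    )
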