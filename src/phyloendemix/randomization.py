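"""Community null models and rank p-values.

The default null is the curveball (fixed-fixed) trade algorithm: repeated
pairwise "trades" between two cells that exchange taxa found in only one
of them, leaving every per-cell richness and per-taxon range exactly
unchanged. This is stricter than richness-only occurrence reallocation; a
``richness`` null (per-cell richness fixed, ranges free) is provided for
fidelity runs. Observed metrics are converted into one-tailed rank
p-values with the +1/(reps+1) convention, so p is never 0 and ties count
toward significance in both tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from numba import njit

from .grid import CommunityMatrix
from .metrics import (
    BranchIncidence,
    branch_incidence,
    make_comparison_tree,
    phylogenetic_endemism,
)

__all__ = ["NullResult", "curveball_randomize", "null_pvalues"]

PVAL_METRICS = ("WE", "CWE", "PE_obs", "PE_alt", "RPE")


@njit(cache=False)
def _curveball_chain(M, idx, ks, n_trades, seed):  # pragma: no cover (jit)
    """Advance the curveball chain in place by ``n_trades`` trades.

    M      : (n_cells, n_taxa) uint8 presence
    idx/ks : per-row taxon index lists (padded) and their lengths
    """
    np.random.seed(seed)
    n_rows = M.shape[0]
    kmax = idx.shape[1]
    only_a = np.empty(kmax, np.int64)
    only_b = np.empty(kmax, np.int64)
    pool = np.empty(2 * kmax, np.int64)
    for _ in range(n_trades):
        i = np.random.randint(0, n_rows)
        j = np.random.randint(0, n_rows)
        if i == j:
            continue
        na = 0
        for p in range(ks[i]):
            t = idx[i, p]
            if M[j, t] == 0:
                only_a[na] = p
                pool[na] = t
                na += 1
        nb = 0
        for p in range(ks[j]):
            t = idx[j, p]
            if M[i, t] == 0:
                only_b[nb] = p
                pool[na + nb] = t
                nb += 1
        if na == 0 or nb == 0:
            continue
        ntot = na + nb
        for p in range(ntot - 1, 0, -1):  # Fisher-Yates
            q = np.random.randint(0, p + 1)
            tmp = pool[p]
            pool[p] = pool[q]
            pool[q] = tmp
        for p in range(ntot):
            t = pool[p]
            M[i, t] = 0
            M[j, t] = 0
        for p in range(na):
            t = pool[p]
            idx[i, only_a[p]] = t
            M[i, t] = 1
        for p in range(nb):
            t = pool[na + p]
            idx[j, only_b[p]] = t
            M[j, t] = 1


class _CurveballState:
    """Mutable chain state over one presence matrix."""

    def __init__(self, presence: np.ndarray):
        self.M = np.ascontiguousarray(presence, dtype=np.uint8).copy()
        ks = self.M.sum(axis=1).astype(np.int64)
        kmax = int(ks.max()) if len(ks) else 0
        idx = np.zeros((self.M.shape[0], max(kmax, 1)), dtype=np.int64)
        for i in range(self.M.shape[0]):
            row = np.nonzero(self.M[i])[0]
            idx[i, : len(row)] = row
        self.idx = idx
        self.ks = ks

    def advance(self, n_trades: int, seed: int) -> None:
        _curveball_chain(self.M, self.idx, self.ks, int(n_trades), int(seed))


def curveball_randomize(
    matrix: CommunityMatrix, n_trades: int, seed: int
) -> CommunityMatrix:
    """One fixed-fixed randomization of the matrix (row and column sums
    preserved exactly)."""
    if n_trades < 0:
        raise ValueError("n_trades must be >= 0")
    if matrix.n_cells < 2 or matrix.n_taxa < 2:
        raise ValueError("need >= 2 cells and >= 2 taxa to randomize")
    state = _CurveballState(matrix.presence)
    state.advance(n_trades, seed)
    return CommunityMatrix(
        presence=state.M,
        cell_ids=matrix.cell_ids.copy(),
        taxon_ids=list(matrix.taxon_ids),
        endemic_mask=matrix.endemic_mask.copy(),
        grid=matrix.grid,
    )


def _richness_null(presence: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Reassign each cell's taxa uniformly at random (richness fixed,
    ranges free)."""
    n_cells, n_taxa = presence.shape
    out = np.zeros_like(presence)
    ks = presence.sum(axis=1)
    for i in range(n_cells):
        out[i, rng.choice(n_taxa, size=int(ks[i]), replace=False)] = 1
    return out


@dataclass
class NullResult:
    """Observed per-cell metrics with one-tailed rank p-values over R
    randomizations: p_high = (#{null >= obs} + 1) / (R + 1), p_low with <=;
    both counts include the observation, so p_high + p_low >= 1 + 1/(R+1).
    """

    cell_ids: np.ndarray
    reps: int
    seed: int
    null: str
    observed: dict = field(default_factory=dict)
    p_high: dict = field(default_factory=dict)
    p_low: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in self.observed:
            rows.append(pd.DataFrame({
                "cell": self.cell_ids,
                "metric": metric,
                "observed": self.observed[metric],
                "p_high": self.p_high[metric],
                "p_low": self.p_low[metric],
            }))
        return pd.concat(rows, ignore_index=True)


def _we(presence: np.ndarray) -> np.ndarray:
    pres = presence.astype(np.float64)
    r = pres.sum(axis=0)
    w = np.zeros_like(r)
    w[r > 0] = 1.0 / r[r > 0]
    return pres @ w


def null_pvalues(
    matrix: CommunityMatrix,
    tree: dendropy.Tree | None = None,
    metrics: tuple[str, ...] = PVAL_METRICS,
    reps: int = 999,
    seed: int = 0,
    null: str = "curveball",
    n_trades: int | None = None,
    burn_in: int | None = None,
    include_root: bool = True,
) -> NullResult:
    """Rank p-values for per-cell metrics under a marginal-preserving null.

    The metrics are computed on the matrix exactly as given — pass the
    endemic submatrix (``matrix.endemic_submatrix()``) for the endemic-only
    analysis. The tree is held fixed across reps; PE/RPE require it.

    The curveball chain burns in for ``burn_in`` trades from the observed
    matrix and then advances ``n_trades`` between successive reps
    (thinning), rather than restarting. Both default to 5x the number of
    presences.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    unknown = set(metrics) - set(PVAL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    need_tree = {"PE_obs", "PE_alt", "RPE"} & set(metrics)
    if need_tree and tree is None:
        raise ValueError(f"metrics {sorted(need_tree)} require a tree")

    fill = int(matrix.presence.sum())
    if n_trades is None:
        n_trades = 5 * fill
    if burn_in is None:
        burn_in = 5 * fill

    inc = inc_alt = None
    if need_tree:
        inc = branch_incidence(tree, matrix, include_root=include_root)
        inc_alt = branch_incidence(
            make_comparison_tree(tree), matrix, include_root=include_root)

    def compute(presence: np.ndarray) -> dict[str, np.ndarray]:
        vals: dict[str, np.ndarray] = {}
        if "WE" in metrics or "CWE" in metrics:
            we = _we(presence)
            if "WE" in metrics:
                vals["WE"] = we
            if "CWE" in metrics:
                sr = presence.sum(axis=1)
                cwe = np.full(len(sr), np.nan)
                cwe[sr > 0] = we[sr > 0] / sr[sr > 0]
                vals["CWE"] = cwe
        if need_tree:
            m = inc.incidence_for(presence)
            pe_obs = phylogenetic_endemism(inc, m)
            pe_alt = phylogenetic_endemism(inc_alt, m)
            if "PE_obs" in metrics:
                vals["PE_obs"] = pe_obs
            if "PE_alt" in metrics:
                vals["PE_alt"] = pe_alt
            if "RPE" in metrics:
                rpe = np.full(len(pe_obs), np.nan)
                ok = pe_alt > 0
                rpe[ok] = pe_obs[ok] / pe_alt[ok]
                vals["RPE"] = rpe
        return vals

    observed = compute(matrix.presence)
    n_cells = matrix.n_cells
    ge = {m: np.zeros(n_cells, dtype=np.int64) for m in observed}
    le = {m: np.zeros(n_cells, dtype=np.int64) for m in observed}
    avail = {m: np.zeros(n_cells, dtype=np.int64) for m in observed}

    ss = np.random.SeedSequence(seed)
    sub_seeds = ss.generate_state(reps + 1) % np.int64(2**31 - 1)
    rng = np.random.default_rng(ss.spawn(1)[0])

    state = None
    if null == "curveball":
        state = _CurveballState(matrix.presence)
        state.advance(burn_in, int(sub_seeds[0]))
    elif null != "richness":
        raise ValueError(f"unknown null model {null!r}")

    for rep in range(reps):
        if null == "curveball":
            state.advance(n_trades, int(sub_seeds[rep + 1]))
            presence = state.M
        else:
            presence = _richness_null(matrix.presence, rng)
        vals = compute(presence)
        for m, v in vals.items():
            obs = observed[m]
            ok = ~(np.isnan(v) | np.isnan(obs))
            ge[m][ok] += v[ok] >= obs[ok]
            le[m][ok] += v[ok] <= obs[ok]
            avail[m][ok] += 1

    result = NullResult(
        cell_ids=matrix.cell_ids.copy(), reps=reps, seed=seed, null=null)
    for m, obs in observed.items():
        denom = avail[m] + 1.0
        result.observed[m] = obs
        result.p_high[m] = (ge[m] + 1.0) / denom
        result.p_low[m] = (le[m] + 1.0) / denom
    return result
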