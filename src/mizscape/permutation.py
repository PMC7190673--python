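"""Edge-vs-interior permutation test for depth-resolved prey backscatter.

Deployments (ice-hole stations) are the exchangeable units: prey backscatter
is strongly autocorrelated across depth within a deployment, so labels
("edge" within 1 km of open water vs "interior" further under the fast ice)
are permuted across whole deployments while depth bins are tested one at a
time.  The observed statistic is

    X = mean(edge values) - mean(interior values)

and the lower-tail p-value is

    p = (1 + sum_j I(x_j <= X)) / (B + 1)

over B random relabelings that keep the edge/interior counts fixed.  A small
lower-tail p means the edge values are unusually low, i.e. greater
backscatter in the interior; the complementary upper tail (I(x_j >= X))
expresses "greater at the edge".  Under an even prey distribution both tails
center on 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .echo import db_to_linear

__all__ = [
    "PermutationResult",
    "permutation_test",
    "deployment_bin_abundance",
    "permutation_depth_table",
    "DEPTH_BIN_EDGES",
]

# 10-m analysis bins over the upper 100 m; deeper comparisons are unreliable
# because single-beam detectability declines with range.
DEPTH_BIN_EDGES = np.arange(0, 101, 10, dtype=float)


@dataclass
class PermutationResult:
    """Outcome of one edge-vs-interior permutation test."""

    statistic: float            # X = mean(edge) - mean(interior)
    n_permutations: int         # B
    p_lower: float              # (1 + #{x_j <= X}) / (B + 1)
    p_upper: float              # (1 + #{x_j >= X}) / (B + 1)
    direction: str              # where backscatter is greater: edge/interior/none
    depth_interval: tuple | None = None
    permuted: np.ndarray | None = None

    @property
    def p(self) -> float:
        """The tail probability matching the observed sign of the statistic."""
        if self.direction == "edge":
            return self.p_upper
        return self.p_lower

    @property
    def significance(self) -> str:
        """Stars: ``**`` at the 95% level, ``*`` at the 90% level."""
        if self.direction == "none":
            return ""
        if self.p <= 0.05:
            return "**"
        if self.p <= 0.10:
            return "*"
        return ""


def permutation_test(
    values,
    is_edge,
    n_permutations: int = 10000,
    seed=None,
    ids=None,
    keep_permuted: bool = False,
    depth_interval=None,
) -> PermutationResult:
    """Permutation test of an edge-interior difference in deployment values.

    Parameters
    ----------
    values : array of per-deployment abundance in one depth bin (zeros common).
    is_edge : boolean array, True for edge deployments.  Class counts are held
        fixed across permutations.
    ids : optional deployment identifiers; when given, inputs are sorted by id
        before drawing permutations so the p-value does not depend on row
        order for a fixed seed.
    """
    values = np.asarray(values, dtype=float)
    is_edge = np.asarray(is_edge, dtype=bool)
    if values.shape != is_edge.shape:
        raise ValueError("values and labels must have the same length")
    if not np.all(np.isfinite(values)):
        raise ValueError("deployment values must be finite")
    n_edge = int(is_edge.sum())
    n_int = int((~is_edge).sum())
    if n_edge < 2 or n_int < 2:
        raise ValueError("need at least 2 deployments in each class")
    if ids is not None:
        order = np.argsort(np.asarray(ids))
        values, is_edge = values[order], is_edge[order]

    x_obs = float(values[is_edge].mean() - values[~is_edge].mean())

    rng = np.random.default_rng(seed)
    n = values.size
    # Random relabelings with fixed class sizes: rank a uniform draw per row,
    # take the lowest n_edge ranks as "edge".
    u = rng.random((n_permutations, n))
    edge_idx = np.argpartition(u, n_edge - 1, axis=1)[:, :n_edge]
    edge_sums = values[edge_idx].sum(axis=1)
    total = values.sum()
    x_perm = edge_sums / n_edge - (total - edge_sums) / n_int

    b = n_permutations
    # tie tolerance at the data's float resolution, so exactly-exchangeable
    # permutations (e.g. constant data) count as equal in both tails
    tol = 1e-12 * max(float(np.max(np.abs(values))), 1e-300)
    p_lower = (1.0 + np.count_nonzero(x_perm <= x_obs + tol)) / (b + 1.0)
    p_upper = (1.0 + np.count_nonzero(x_perm >= x_obs - tol)) / (b + 1.0)
    direction = "edge" if x_obs > tol else ("interior" if x_obs < -tol else "none")
    return PermutationResult(
        statistic=x_obs,
        n_permutations=b,
        p_lower=float(p_lower),
        p_upper=float(p_upper),
        direction=direction,
        depth_interval=depth_interval,
        permuted=x_perm if keep_permuted else None,
    )


def deployment_bin_abundance(
    cells: pd.DataFrame,
    station_table: pd.DataFrame,
    taxon: str,
    depth_edges=DEPTH_BIN_EDGES,
    statistic: str = "sum",
) -> pd.DataFrame:
    """Per-deployment linear-domain abundance of one taxon in 10-m depth bins.

    ``cells`` is the per-cell table from classified aggregations
    (``station_id, taxon, depth_mid_m, sv_db``).  Every station in
    ``station_table`` gets a row per bin; stations with no classified cells
    in a bin score 0 (prey absent, a real observation).  ``statistic`` is the
    linear-domain ``sum`` (default) or ``mean`` over contributing cells.
    """
    if statistic not in ("sum", "mean"):
        raise ValueError("statistic must be 'sum' or 'mean'")
    depth_edges = np.asarray(depth_edges, dtype=float)
    stations = station_table[["station_id", "location_class"]].copy()
    bins = pd.DataFrame({"depth_bin": np.arange(len(depth_edges) - 1)})
    base = stations.merge(bins, how="cross")
    base["abundance"] = 0.0

    sub = cells[cells["taxon"] == taxon].copy()
    if len(sub):
        sub = sub[(sub["depth_mid_m"] >= depth_edges[0]) & (sub["depth_mid_m"] < depth_edges[-1])]
    if len(sub):
        sub["depth_bin"] = np.digitize(sub["depth_mid_m"], depth_edges) - 1
        sub["linear"] = db_to_linear(sub["sv_db"])
        agg = (
            sub.groupby(["station_id", "depth_bin"])["linear"]
            .agg(statistic)
            .rename("abundance")
            .reset_index()
        )
        base = base.drop(columns="abundance").merge(
            agg, on=["station_id", "depth_bin"], how="left"
        )
        base["abundance"] = base["abundance"].fillna(0.0)
    base["depth_lo"] = depth_edges[base["depth_bin"].to_numpy()]
    base["depth_hi"] = depth_edges[base["depth_bin"].to_numpy() + 1]
    return base


def permutation_depth_table(
    cells: pd.DataFrame,
    station_table: pd.DataFrame,
    taxa=("krill", "silverfish"),
    depth_edges=DEPTH_BIN_EDGES,
    n_permutations: int = 10000,
    seed=None,
    statistic: str = "sum",
) -> pd.DataFrame:
    """Run the permutation test per taxon and 10-m depth bin (0-100 m).

    Returns one row per (taxon, depth interval) with the observed statistic,
    the sign-matched p-value, the location of greater backscatter and
    significance stars.  A taxon absent from every deployment is omitted with
    a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for taxon in taxa:
        table = deployment_bin_abundance(cells, station_table, taxon, depth_edges, statistic)
        if not (table["abundance"] > 0).any():
            warnings.warn(f"taxon {taxon!r} absent from all deployments; omitted")
            continue
        for b, grp in table.groupby("depth_bin"):
            res = permutation_test(
                grp["abundance"].to_numpy(),
                (grp["location_class"] == "edge").to_numpy(),
                n_permutations=n_permutations,
                seed=rng.integers(2**31),
                ids=grp["station_id"].to_numpy(),
                depth_interval=(grp["depth_lo"].iloc[0], grp["depth_hi"].iloc[0]),
            )
            rows.append(
                {
                    "taxon": taxon,
                    "depth_lo_m": res.depth_interval[0],
                    "depth_hi_m": res.depth_interval[1],
                    "statistic": res.statistic,
                    "p_value": res.p,
                    "p_lower": res.p_lower,
                    "p_upper": res.p_upper,
                    "greater_at": res.direction if res.significance else "-",
                    "significance": res.significance,
                }
            )
    return pd.DataFrame(rows)
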