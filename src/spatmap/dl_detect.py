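"""Differential localization between two cell lines' spatial maps.

Because whole organelle profiles can shift systematically between cell
lines, translocations are not detected by comparing profiles directly.
Instead each protein's position is expressed *within* its own map as a
vector of Mahalanobis distances to every SVM-classified compartment
(robust MCD covariance), and two maps are compared through these
distance profiles:

1. qualitative stage — proteins confidently classified to different
   compartments in the two combined maps;
2. quantitative stage — proteins whose closest compartment (smallest
   Mahalanobis distance on the combined maps) changes between
   conditions, with the replicate-level distances to both closest
   compartments significantly different (two-sided t test,
   Benjamini-Hochberg FDR over all protein x compartment tests).

Compositional profiles are rank-deficient (rows sum to 1), so all
covariance work happens after an isometric projection onto the
orthogonal complement of the all-ones direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .classify import UNKNOWN, ClassifiedMap
from .io_preprocess import ProfileMatrix

logger = logging.getLogger(__name__)

NUCLEAR_LABELS = ("nucleus_chromatin", "nucleus_nonchromatin")
MERGED_NUCLEUS = "nucleus"


@dataclass
class CompartmentStats:
    """Robust location/scatter of one compartment in reduced coordinates."""

    compartment: str
    center: np.ndarray
    covariance: np.ndarray
    precision: np.ndarray
    n_members: int


@dataclass
class DistanceProfileSet:
    """Per protein x replicate Mahalanobis distances to each compartment.

    ``distances`` has a (accession, replicate) MultiIndex and one
    column per compartment of the (possibly nucleus-merged) taxonomy.
    """

    distances: pd.DataFrame
    condition: str
    taxonomy: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.distances.to_numpy() < 0).any():
            raise ValueError("distances must be nonnegative")
        if tuple(self.distances.columns) != self.taxonomy:
            raise ValueError("distance columns must match the taxonomy order")

    @property
    def replicates(self) -> list:
        return sorted(self.distances.index.get_level_values("replicate").unique())


def merge_nuclear(cmap: ClassifiedMap) -> ClassifiedMap:
    """Collapse the chromatin / non-chromatin classes into one nucleus.

    Needed to compare an 11-class map (subnuclear resolution) with a
    10-class one. Idempotent; marker counts are conserved.
    """
    present = [c for c in NUCLEAR_LABELS if c in cmap.taxonomy]
    if not present:
        return cmap
    taxonomy: list[str] = []
    for c in cmap.taxonomy:
        if c in NUCLEAR_LABELS:
            if MERGED_NUCLEUS not in taxonomy:
                taxonomy.append(MERGED_NUCLEUS)
        else:
            taxonomy.append(c)
    assignments = cmap.assignments.copy()
    assignments["predicted"] = assignments["predicted"].replace(
        dict.fromkeys(NUCLEAR_LABELS, MERGED_NUCLEUS)
    )
    return ClassifiedMap(
        profiles=cmap.profiles,
        assignments=assignments,
        taxonomy=tuple(taxonomy),
        threshold=cmap.threshold,
    )


def qualitative_dl(map_a: ClassifiedMap, map_b: ClassifiedMap) -> list[str]:
    """Proteins confidently classified to different compartments.

    Only proteins that are non-"unknown" in both combined maps are
    eligible; proteins unknown in either map are left to the
    quantitative stage.
    """
    overlap = map_a.assignments.index.intersection(map_b.assignments.index)
    if len(overlap) == 0:
        raise ValueError("no overlapping proteins between the maps")
    pa = map_a.predicted.loc[overlap]
    pb = map_b.predicted.loc[overlap]
    mask = (pa != UNKNOWN) & (pb != UNKNOWN) & (pa != pb)
    return overlap[mask].tolist()


def reduction_basis(n_fractions: int) -> np.ndarray:
    """Orthonormal basis of the complement of the all-ones direction."""
    return helmert(n_fractions, full=False)


def compartment_stats(
    profiles: ProfileMatrix | pd.DataFrame,
    members: pd.Index | list[str],
    compartment: str = "",
    estimator: str = "mcd",
    support_fraction: float | None = None,
    reduce: bool = True,
    seed: int = 0,
) -> CompartmentStats:
    """Robust center and scatter of one compartment's member profiles.

    Member profiles are projected into full-rank coordinates, a
    minimum-covariance-determinant (or, optionally, empirical)
    estimate is fitted, and a ridge floor of 1e-8 * trace/dim keeps the
    scatter positive definite even for degenerate clusters. Requires
    at least dim + 2 members.
    """
    data = profiles.data if isinstance(profiles, ProfileMatrix) else profiles
    members = pd.Index(members).intersection(data.index)
    X = data.loc[members].to_numpy(dtype=float)
    if reduce:
        X = X @ reduction_basis(data.shape[1]).T
    dim = X.shape[1]
    if len(X) < dim + 2:
        raise ValueError(
            f"compartment {compartment or '?'} has {len(X)} members; "
            f"needs >= {dim + 2} for covariance estimation"
        )
    spread = float(np.var(X, axis=0).sum())
    if estimator == "mcd" and spread > 1e-20:
        mcd = MinCovDet(support_fraction=support_fraction, random_state=seed)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rank warnings; ridge floor below
            try:
                mcd.fit(X)
                center, cov = mcd.location_, mcd.covariance_
            except ValueError:
                # support covariance exactly zero: duplicate-heavy cluster
                center = X.mean(axis=0)
                cov = np.cov(X, rowvar=False)
    elif estimator == "mcd":
        # members (near-)identical: center is the common profile
        center = X.mean(axis=0)
        cov = np.zeros((dim, dim))
    elif estimator == "empirical":
        center = X.mean(axis=0)
        cov = np.cov(X, rowvar=False)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    tr = np.trace(cov)
    ridge = 1e-8 * tr / dim if tr > 0 else 1e-12
    cov = cov + ridge * np.eye(dim)
    precision = np.linalg.inv(cov)
    return CompartmentStats(
        compartment=compartment,
        center=center,
        covariance=cov,
        precision=precision,
        n_members=len(X),
    )


def distance_profile(
    x: np.ndarray,
    stats_by_comp: dict[str, CompartmentStats],
    reduce: bool = True,
) -> pd.Series:
    """Mahalanobis distance of one profile to every compartment."""
    x = np.asarray(x, dtype=float)
    if reduce:
        x = x @ reduction_basis(len(x)).T
    out = {}
    for comp, st in stats_by_comp.items():
        diff = x - st.center
        d2 = float(diff @ st.precision @ diff)
        out[comp] = np.sqrt(max(d2, 0.0))
    return pd.Series(out)


def _distance_matrix(
    data: pd.DataFrame, stats_by_comp: dict[str, CompartmentStats]
) -> pd.DataFrame:
    """Mahalanobis distances of every row profile to every compartment."""
    X = data.to_numpy(dtype=float) @ reduction_basis(data.shape[1]).T
    cols = {}
    for comp, st in stats_by_comp.items():
        diff = X - st.center
        d2 = np.einsum("ij,jk,ik->i", diff, st.precision, diff)
        cols[comp] = np.sqrt(np.clip(d2, 0.0, None))
    return pd.DataFrame(cols, index=data.index)


def closest_compartment(
    distances: pd.Series, taxonomy: tuple[str, ...] | None = None
) -> str:
    """Compartment with the smallest Mahalanobis distance.

    Ties are broken by taxonomy order, with a warning.
    """
    if not np.isfinite(distances.to_numpy()).all():
        raise ValueError("distances must be finite")
    order = list(taxonomy) if taxonomy is not None else list(distances.index)
    d = distances.reindex(order)
    dmin = d.min()
    winners = d.index[d == dmin]
    if len(winners) > 1:
        logger.warning(
            "distance tie between %s; keeping %s (taxonomy order)",
            list(winners), winners[0],
        )
    return str(winners[0])


def compartment_membership(cmap: ClassifiedMap) -> dict[str, pd.Index]:
    """SVM-classified members (markers included) per compartment."""
    return {
        comp: cmap.members(comp)
        for comp in cmap.taxonomy
        if len(cmap.members(comp)) > 0
    }


def build_distance_profiles(
    replicate_maps: list[ProfileMatrix],
    membership: dict[str, pd.Index],
    taxonomy: tuple[str, ...],
    condition: str,
    seed: int = 0,
    stats_by_comp: dict[str, CompartmentStats] | None = None,
) -> DistanceProfileSet:
    """Replicate-level distance profiles to each compartment.

    With ``stats_by_comp`` supplied (typically fitted on the combined
    map), every replicate's profiles are measured against that shared,
    well-estimated geometry, so replicate-to-replicate distance
    variation reflects only profile noise. Without it, MCD
    location/scatter are re-estimated per replicate from the member
    proteins present in that replicate.
    """
    frames = []
    for r, pmap in enumerate(replicate_maps, start=1):
        if stats_by_comp is None:
            rep_stats = {
                comp: compartment_stats(
                    pmap, members, compartment=comp, seed=seed + r
                )
                for comp, members in membership.items()
            }
        else:
            rep_stats = stats_by_comp
        dm = _distance_matrix(pmap.data, rep_stats)
        dm = dm.reindex(columns=[c for c in taxonomy if c in dm.columns])
        dm.index = pd.MultiIndex.from_product(
            [dm.index, [r]], names=["accession", "replicate"]
        )
        frames.append(dm)
    distances = pd.concat(frames)
    present = tuple(distances.columns)
    return DistanceProfileSet(distances=distances, condition=condition, taxonomy=present)


def combined_closest_compartments(
    cmap: ClassifiedMap, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame]:
    """Closest compartment of every protein on a combined map.

    Returns the per-protein closest compartment and the full distance
    matrix, both computed against MCD stats of the combined map's
    SVM-classified members.
    """
    membership = compartment_membership(cmap)
    usable = {
        c: m for c, m in membership.items()
        if c != UNKNOWN and len(m) >= cmap.profiles.n_fractions + 1
    }
    stats_by_comp = {
        comp: compartment_stats(cmap.profiles, members, compartment=comp, seed=seed)
        for comp, members in usable.items()
    }
    dm = _distance_matrix(cmap.profiles.data, stats_by_comp)
    order = [c for c in cmap.taxonomy if c in dm.columns]
    dm = dm[order]
    closest = pd.Series(
        dm.columns[np.argmin(dm.to_numpy(), axis=1)], index=dm.index, name="closest"
    )
    return closest, dm


def test_dl(
    profiles_a: DistanceProfileSet,
    profiles_b: DistanceProfileSet,
    closest_a: pd.Series,
    closest_b: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Quantitative differential-localization test.

    Per protein and compartment, replicate distances of condition A are
    compared with condition B by a two-sided two-sample t test;
    p-values are BH-adjusted over the whole protein x compartment
    family. A protein is differentially localized if its closest
    compartment (from the combined maps) changes between conditions
    and the distances to both closest compartments are significant.
    """
    common_comps = [c for c in profiles_a.taxonomy if c in profiles_b.taxonomy]
    if not common_comps:
        raise ValueError("no shared compartments between the two conditions")
    da = profiles_a.distances[common_comps]
    db = profiles_b.distances[common_comps]
    prots = (
        da.index.get_level_values("accession")
        .unique()
        .intersection(db.index.get_level_values("accession").unique())
        .intersection(closest_a.index)
        .intersection(closest_b.index)
    )
    if len(prots) == 0:
        raise ValueError("no proteins shared between the two distance sets")

    def stack(df: pd.DataFrame, reps: list) -> np.ndarray:
        # (protein, compartment, replicate) array over the common proteins
        wide = df.unstack("replicate")
        wide = wide.reindex(
            columns=pd.MultiIndex.from_product([common_comps, reps])
        ).loc[prots]
        return wide.to_numpy().reshape(len(prots), len(common_comps), len(reps))

    arr_a = stack(da, profiles_a.replicates)
    arr_b = stack(db, profiles_b.replicates)
    complete = np.isfinite(arr_a).all(axis=(1, 2)) & np.isfinite(arr_b).all(axis=(1, 2))
    prots, arr_a, arr_b = prots[complete], arr_a[complete], arr_b[complete]
    if len(prots) == 0:
        raise ValueError("no proteins with complete replicate distance profiles")
    if arr_a.shape[2] < 2 or arr_b.shape[2] < 2:
        raise ValueError("need >= 2 replicates per condition")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows
        tt = stats.ttest_ind(arr_a, arr_b, axis=2)
    pvals = np.asarray(tt.pvalue, dtype=float)
    mean_diff = arr_a.mean(axis=2) - arr_b.mean(axis=2)
    degenerate = ~np.isfinite(pvals)
    if degenerate.any():
        zero_diff = np.isclose(mean_diff, 0.0)
        n_sig = int((degenerate & ~zero_diff).sum())
        if n_sig:
            logger.warning(
                "%d zero-variance distance tests with unequal means; "
                "treated as significant", n_sig,
            )
        pvals[degenerate & zero_diff] = 1.0
        pvals[degenerate & ~zero_diff] = np.nextafter(0.0, 1.0)
    qvals = multipletests(pvals.ravel(), method="fdr_bh")[1].reshape(pvals.shape)

    p_df = pd.DataFrame(pvals, index=prots, columns=common_comps)
    q_df = pd.DataFrame(qvals, index=prots, columns=common_comps)
    ca = closest_a.loc[prots]
    cb = closest_b.loc[prots]
    rows = []
    for i, acc in enumerate(prots):
        a_comp, b_comp = ca.iloc[i], cb.iloc[i]
        q_a = q_df.at[acc, a_comp] if a_comp in q_df.columns else np.nan
        q_b = q_df.at[acc, b_comp] if b_comp in q_df.columns else np.nan
        is_dl = bool(
            a_comp != b_comp
            and np.isfinite(q_a)
            and np.isfinite(q_b)
            and q_a <= alpha
            and q_b <= alpha
        )
        rows.append((acc, a_comp, b_comp, q_a, q_b, is_dl))
    result = pd.DataFrame(
        rows,
        columns=["accession", "closest_A", "closest_B", "q_A", "q_B", "is_DL"],
    ).set_index("accession")
    result.attrs["p_values"] = p_df
    result.attrs["q_values"] = q_df
    result.attrs["alpha"] = alpha
    return result


def collate_dl(
    qualitative: list[str], quantitative: pd.DataFrame
) -> pd.DataFrame:
    """Union of the two detection stages, one row per protein.

    Rows are tagged ``qualitative``, ``quantitative`` or
    ``qualitative+quantitative``.
    """
    quant_hits = quantitative.index[quantitative["is_DL"]]
    all_accs = sorted(set(qualitative) | set(quant_hits))
    rows = []
    for acc in all_accs:
        stages = []
        if acc in qualitative:
            stages.append("qualitative")
        if acc in quant_hits:
            stages.append("quantitative")
        if acc in quantitative.index:
            rec = quantitative.loc[acc]
            rows.append(
                (acc, "+".join(stages), rec["closest_A"], rec["closest_B"],
                 rec["q_A"], rec["q_B"])
            )
        else:
            rows.append((acc, "+".join(stages), np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=["accession", "stage", "closest_A", "closest_B", "q_A", "q_B"],
    ).set_index("accession")


def _merge_nuclear_columns(
    distances: pd.DataFrame, merged_taxonomy: tuple[str, ...]
) -> pd.DataFrame:
    """Collapse sub-nuclear distance columns into one nucleus column.

    The distance to a union of clusters is the distance to its nearest
    component, so the merged column takes the row-wise minimum.
    """
    nuclear = [c for c in NUCLEAR_LABELS if c in distances.columns]
    if not nuclear:
        return distances
    out = distances.drop(columns=nuclear)
    out[MERGED_NUCLEUS] = distances[nuclear].min(axis=1)
    return out[[c for c in merged_taxonomy if c in out.columns]]


def run_dl_analysis(
    combined_a: ClassifiedMap,
    combined_b: ClassifiedMap,
    replicates_a: list[ProfileMatrix],
    replicates_b: list[ProfileMatrix],
    alpha: float = 0.05,
    seed: int = 0,
    stats_source: str = "combined",
) -> dict:
    """Full two-stage differential-localization workflow.

    Both combined maps are nucleus-merged onto a common taxonomy;
    membership for the distance statistics comes from each condition's
    combined-map classification. By default the robust compartment
    statistics are fitted once per condition on the combined map and
    each replicate's profiles are measured against them
    (``stats_source="combined"``); ``stats_source="replicate"``
    re-estimates the statistics within every replicate map instead.
    """
    if stats_source not in ("combined", "replicate"):
        raise ValueError(f"unknown stats_source {stats_source!r}")
    map_a = merge_nuclear(combined_a)
    map_b = merge_nuclear(combined_b)
    qual = qualitative_dl(map_a, map_b)

    results = {}
    dps = {}
    closest = {}
    for cond, cmap, merged, reps in (
        ("A", combined_a, map_a, replicates_a),
        ("B", combined_b, map_b, replicates_b),
    ):
        # statistics are fitted on the unmerged classes (a merged nucleus
        # is bimodal and would defeat the MCD); nuclear distance columns
        # are collapsed to their minimum afterwards
        membership = {
            c: m for c, m in compartment_membership(cmap).items()
            if c != UNKNOWN and len(m) >= cmap.profiles.n_fractions + 1
        }
        combined_stats = {
            comp: compartment_stats(
                cmap.profiles, members, compartment=comp, seed=seed
            )
            for comp, members in membership.items()
        }
        dp = build_distance_profiles(
            reps, membership, cmap.taxonomy, condition=cond, seed=seed,
            stats_by_comp=combined_stats if stats_source == "combined" else None,
        )
        dist = _merge_nuclear_columns(dp.distances, merged.taxonomy)
        dps[cond] = DistanceProfileSet(
            distances=dist, condition=cond, taxonomy=tuple(dist.columns)
        )
        dm = _distance_matrix(cmap.profiles.data, combined_stats)
        dm = _merge_nuclear_columns(
            dm[[c for c in cmap.taxonomy if c in dm.columns]], merged.taxonomy
        )
        closest[cond] = pd.Series(
            dm.columns[np.argmin(dm.to_numpy(), axis=1)], index=dm.index,
            name="closest",
        )
    quant = test_dl(dps["A"], dps["B"], closest["A"], closest["B"], alpha=alpha)
    results["qualitative"] = qual
    results["quantitative"] = quant
    results["collated"] = collate_dl(qual, quant)
    results["distance_profiles"] = dps
    results["closest"] = closest
    return results
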