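"""Hit calling for the primary and secondary siRNA screens and K-means
phenotype triage.

Primary screen: an siRNA pool is a down-hit when its B-score falls at or
below the down cutoff in at least ``min_replicates`` of ``n_replicates``
replicates for *both* cytokine readouts (IL-8 and IL-6); up-hits mirror the
rule at the up cutoff.  The symmetric defaults (-2 / +2 B-score units, the
+/-2 SD scramble band) are used; an as-printed asymmetric mode
(down < -2, up > 3) is selectable.

Secondary screen: each siRNA's three replicate NPI values are compared with
all scramble NPI values by a two-sided pooled-variance (Student) t-test; an
siRNA qualifies on a readout when its mean NPI is below the cutoff (default
0.8, i.e. at least 20% inhibition) with p <= alpha, and a gene validates
when at least two of its siRNAs qualify on both readouts.

Phenotype triage: SASP-repressing siRNAs are clustered on their senescence
B-score profiles (p16, p21, BrdU per replicate) with K-means (k = 4), and
the cluster centroids are labelled by how they deviate from the scramble
reference: arrest-reverted, arrest-exacerbated, or SASP-only (the cluster of
interest: SASP down without reverting the growth arrest).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .exceptions import CoverageError, DegenerateInputError, ParameterError


def _replicate_pivot(bscores: pd.DataFrame, unit: str, readouts: list[str]):
    """Pivot a long B-score table to arrays (n_units, n_readouts, n_reps)."""
    sub = bscores[bscores["readout"].isin(readouts)]
    wide = sub.pivot_table(
        index=unit, columns=["readout", "replicate"], values="b", aggfunc="first"
    )
    return wide


def call_primary_hits(
    bscores: pd.DataFrame,
    readouts: tuple[str, str] = ("IL8", "IL6"),
    down_cutoff: float = -2.0,
    up_cutoff: float = 2.0,
    min_replicates: int = 2,
    n_replicates: int = 3,
    as_printed: bool = False,
    unit: str = "gene_id",
) -> pd.DataFrame:
    """Primary-screen hit calls from a long B-score table.

    ``bscores`` columns: ``unit`` (gene_id by default), replicate, readout,
    b.  ``as_printed=True`` applies the strict-inequality asymmetric rule
    (down < -2, up > 3) exactly as printed in the screen legend.

    Returns one row per unit: direction in {down, up, none} plus per-readout
    replicate pass counts.
    """
    if as_printed:
        down_cutoff, up_cutoff = -2.0, 3.0

    readouts = list(readouts)
    wide = _replicate_pivot(bscores, unit, readouts)
    for r in readouts:
        if r not in wide.columns.get_level_values(0):
            raise CoverageError(f"readout {r} missing from B-score table")
        counts = wide[r].notna().sum(axis=1)
        if (counts < min_replicates).any():
            bad = counts.index[counts < min_replicates][0]
            raise CoverageError(
                f"{unit} {bad}: fewer than {min_replicates} replicates for {r}"
            )

    out = pd.DataFrame(index=wide.index)
    down_all = np.ones(len(wide), dtype=bool)
    up_all = np.ones(len(wide), dtype=bool)
    for r in readouts:
        vals = wide[r]
        if as_printed:
            n_down = (vals < down_cutoff).sum(axis=1)
            n_up = (vals > up_cutoff).sum(axis=1)
        else:
            n_down = (vals <= down_cutoff).sum(axis=1)
            n_up = (vals >= up_cutoff).sum(axis=1)
        out[f"n_down_{r}"] = n_down
        out[f"n_up_{r}"] = n_up
        down_all &= (n_down >= min_replicates).to_numpy()
        up_all &= (n_up >= min_replicates).to_numpy()
    out["direction"] = np.where(down_all, "down", np.where(up_all, "up", "none"))
    out["rule_version"] = "as_printed" if as_printed else "symmetric"
    return out.reset_index()


def secondary_validation(
    npi_table: pd.DataFrame,
    scramble_values: dict[str, np.ndarray],
    npi_cutoff: float = 0.8,
    alpha: float = 0.05,
    min_sirnas: int = 2,
    readouts: tuple[str, str] = ("IL8", "IL6"),
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Secondary-screen validation against scramble controls.

    ``npi_table`` columns: sirna_id, gene_id, readout, replicate, npi.
    ``scramble_values`` maps readout -> array of all scramble NPI values.

    Returns ``(per_sirna, per_gene)``: the per-siRNA/readout table with mean
    NPI, t, p and the qualify flag, and the gene table with the gene_pass
    flag (>= ``min_sirnas`` siRNAs qualifying on both readouts).
    """
    readouts = list(readouts)
    rows = []
    for readout in readouts:
        scr = np.asarray(scramble_values[readout], dtype=float)
        if scr.size < 2:
            raise DegenerateInputError(f"need >=2 scramble values for {readout}")
        sub = npi_table[npi_table["readout"] == readout]
        piv = sub.pivot_table(
            index=["sirna_id", "gene_id"], columns="replicate", values="npi",
            aggfunc="first",
        )
        x = piv.to_numpy(dtype=float)
        n1 = x.shape[1]
        m1 = x.mean(axis=1)
        v1 = x.var(axis=1, ddof=1)
        n2, m2, v2 = scr.size, scr.mean(), scr.var(ddof=1)
        if welch:
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            if np.any(sp2 == 0):
                bad = piv.index[np.where(sp2 == 0)[0][0]][0]
                raise DegenerateInputError(
                    f"siRNA {bad}: zero pooled variance for {readout}"
                )
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = np.full(len(m1), n1 + n2 - 2)
        t = (m1 - m2) / se
        p = 2 * stats.t.sf(np.abs(t), df)
        qualify = (m1 < npi_cutoff) & (p <= alpha)
        for (sid, gid), mm, tt, pp, qq in zip(piv.index, m1, t, p, qualify):
            rows.append(
                dict(sirna_id=sid, gene_id=gid, readout=readout,
                     npi_mean=float(mm), t=float(tt), p=float(pp),
                     qualify=bool(qq))
            )
    per_sirna = pd.DataFrame(rows)
    both = (
        per_sirna.groupby(["sirna_id", "gene_id"])["qualify"]
        .agg(lambda q: bool(q.all()) and len(q) == len(readouts))
        .rename("qualifies_both")
        .reset_index()
    )
    per_gene = (
        both.groupby("gene_id")["qualifies_both"]
        .agg(n_qualifying="sum", n_sirnas="count")
        .reset_index()
    )
    per_gene["gene_pass"] = per_gene["n_qualifying"] >= min_sirnas
    return per_sirna, per_gene


def kmeans_cluster(
    profiles: pd.DataFrame,
    feature_columns: list[str],
    k: int = 4,
    n_init: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """K-means clustering of phenotype profiles on raw B-score features.

    Lloyd's algorithm with k-means++ initialization and ``n_init`` restarts
    (best by within-cluster sum of squares), Euclidean distance, deterministic
    under a fixed seed.  Returns the profiles with a 1-based ``cluster_id``
    column and the (k, n_features) centroid matrix.
    """
    x = profiles[feature_columns].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ParameterError("profile features must be finite")
    if k > len(profiles):
        raise ParameterError(f"k = {k} exceeds the {len(profiles)} profiles")
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++", random_state=seed)
    labels = km.fit_predict(x)
    out = profiles.copy()
    out["cluster_id"] = labels + 1
    return out, km.cluster_centers_


CLUSTER_ROLES = ("arrest_reverted", "arrest_exacerbated", "sasp_only", "other")


def label_clusters(
    centroids: np.ndarray,
    feature_columns: list[str],
    reference: dict[str, float] | None = None,
    reversion_margin: float = 2.0,
    brdu_feature: str = "BrdU",
    p16_feature: str = "p16",
    p21_feature: str = "p21",
) -> list[str]:
    """Assign phenotype roles to K-means centroids.

    Deviations are measured from the scramble/induced reference profile
    (default: all-zero B-scores).  Rules, applied in precedence order
    reverted > exacerbated > sasp_only:

    * arrest_reverted: BrdU deviation >= +margin and p16 or p21 <= -margin;
    * arrest_exacerbated: p21 deviation >= +margin;
    * sasp_only: |BrdU|, |p16| and |p21| deviations all < margin;
    * other: anything else.

    Feature columns may carry replicate suffixes (``p16_r1``); deviations
    are averaged over the columns matching each marker prefix.
    """
    ref = reference or {}

    def marker_dev(centroid, marker):
        cols = [i for i, c in enumerate(feature_columns)
                if c == marker or c.startswith(marker + "_")]
        if not cols:
            raise ParameterError(f"no feature column for marker {marker}")
        base = ref.get(marker, 0.0)
        return float(np.mean([centroid[i] for i in cols])) - base

    roles = []
    for c in np.asarray(centroids, dtype=float):
        brdu = marker_dev(c, brdu_feature)
        p16 = marker_dev(c, p16_feature)
        p21 = marker_dev(c, p21_feature)
        if brdu >= reversion_margin and (p16 <= -reversion_margin or p21 <= -reversion_margin):
            roles.append("arrest_reverted")
        elif p21 >= reversion_margin:
            roles.append("arrest_exacerbated")
        elif max(abs(brdu), abs(p16), abs(p21)) < reversion_margin:
            roles.append("sasp_only")
        else:
            roles.append("other")
    return roles
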