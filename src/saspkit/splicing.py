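"""Percent-spliced-in quantification, differential-splicing tests and
event shortlisting.

For a cassette exon with junction reads ``inc1`` (upstream exon -> cassette),
``inc2`` (cassette -> downstream exon) and ``skip`` (upstream -> downstream),
the inclusion evidence is averaged over the two inclusion junctions,
``I = (inc1 + inc2) / 2`` (a cassette exon contributes two inclusion
junctions but only one skipping junction), and

    PSI = I / (I + skip).

Differential splicing between two conditions is tested with Fisher's exact
test on the pooled 2x2 table [rounded I, skip] x [condition A, B];
inclusion-level changes are summarized as ``delta PSI = PSI_B - PSI_A`` and
classified with the |delta PSI| >= 0.2 and FDR < 0.05 rules.  By the
knockdown - control direction convention, exons whose inclusion rises when
the repressor is depleted (positive delta PSI) are classed as repressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    CoverageError,
    DegenerateInputError,
    FormatError,
    SampleSizeError,
)
from .io_formats import EVENT_TYPES

REGULATION_CLASSES = ("repressed", "enhanced", "unchanged")


@dataclass
class PsiEstimate:
    psi: float
    effective_coverage: float


def psi_from_junctions(inc1: int, inc2: int, skip: int) -> PsiEstimate:
    """PSI from cassette-exon junction read counts."""
    if min(inc1, inc2, skip) < 0:
        raise DegenerateInputError("junction counts must be non-negative")
    inclusion = (inc1 + inc2) / 2.0
    total = inclusion + skip
    if total == 0:
        raise DegenerateInputError("all junction counts are zero: PSI undefined")
    return PsiEstimate(psi=inclusion / total, effective_coverage=total)


def psi_from_concentrations(c_long: float, c_short: float) -> PsiEstimate:
    """PSI from fragment concentrations of the two RT-PCR products: the
    concentration of the larger (exon-included) product relative to the sum."""
    if c_long < 0 or c_short < 0:
        raise DegenerateInputError("concentrations must be non-negative")
    total = c_long + c_short
    if total == 0:
        raise DegenerateInputError("both concentrations zero: PSI undefined")
    return PsiEstimate(psi=c_long / total, effective_coverage=total)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class DeltaPsiRecord:
    event_id: str
    delta_psi: float
    p: float
    psi_a: float
    psi_b: float
    degenerate: bool = False
    fdr: float = float("nan")
    regulation_class: str = "unchanged"


def delta_psi_test(
    counts_a: tuple[int, int, int],
    counts_b: tuple[int, int, int],
    event_id: str = "",
) -> DeltaPsiRecord:
    """Fisher's exact test on pooled junction counts of two conditions.

    ``counts_* = (inc1, inc2, skip)`` pooled over replicates.  Inclusion is
    averaged over the two junctions and rounded half-up before forming the
    2x2 table.  A table with a zero margin is reported as p = 1 with the
    degenerate flag set.
    """
    est_a = psi_from_junctions(*counts_a)
    est_b = psi_from_junctions(*counts_b)
    ia = _round_half_up((counts_a[0] + counts_a[1]) / 2.0)
    ib = _round_half_up((counts_b[0] + counts_b[1]) / 2.0)
    sa, sb = counts_a[2], counts_b[2]
    table = np.array([[ia, sa], [ib, sb]])
    degenerate = bool((table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any())
    if degenerate:
        p = 1.0
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    return DeltaPsiRecord(
        event_id=event_id,
        delta_psi=est_b.psi - est_a.psi,
        p=float(p),
        psi_a=est_a.psi,
        psi_b=est_b.psi,
        degenerate=degenerate,
    )


def delta_psi_table(
    junctions: pd.DataFrame,
    condition_a: str,
    condition_b: str,
) -> pd.DataFrame:
    """Run :func:`delta_psi_test` for every event of a long junction table.

    ``junctions`` columns: event_id, sample_id, condition, inc1, inc2, skip.
    Replicates are pooled by summing counts within each condition.
    """
    pooled = (
        junctions[junctions["condition"].isin([condition_a, condition_b])]
        .groupby(["event_id", "condition"], sort=False)[["inc1", "inc2", "skip"]]
        .sum()
    )
    recs = []
    for event_id in junctions["event_id"].drop_duplicates():
        try:
            a = pooled.loc[(event_id, condition_a)]
            b = pooled.loc[(event_id, condition_b)]
        except KeyError:
            raise CoverageError(
                f"event {event_id}: missing counts for one of the conditions"
            ) from None
        r = delta_psi_test(
            (int(a["inc1"]), int(a["inc2"]), int(a["skip"])),
            (int(b["inc1"]), int(b["inc2"]), int(b["skip"])),
            event_id=event_id,
        )
        recs.append(
            dict(event_id=r.event_id, psi_a=r.psi_a, psi_b=r.psi_b,
                 delta_psi=r.delta_psi, p=r.p, degenerate=r.degenerate)
        )
    return pd.DataFrame(recs)


def classify_regulation(
    records: pd.DataFrame,
    delta_cutoff: float = 0.2,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Assign each event a regulation class from its delta PSI and FDR.

    ``records`` must carry ``delta_psi`` and ``fdr`` columns (FDR filled by
    Benjamini-Hochberg over all tested events).  Rules: repressed iff
    delta_psi >= delta_cutoff and fdr < fdr_cutoff; enhanced iff
    delta_psi <= -delta_cutoff and fdr < fdr_cutoff; otherwise unchanged.
    """
    out = records.copy()
    sig = out["fdr"] < fdr_cutoff
    cls = np.where(
        sig & (out["delta_psi"] >= delta_cutoff),
        "repressed",
        np.where(sig & (out["delta_psi"] <= -delta_cutoff), "enhanced", "unchanged"),
    )
    out["regulation_class"] = cls
    return out


def shortlist_events(
    records_test: pd.DataFrame,
    records_reference: pd.DataFrame,
    base_cutoff: float = 0.2,
    strict_cutoff: float = 0.3,
) -> pd.DataFrame:
    """Two-tier shortlist of events regulated in the test contrast.

    Tier 1: events regulated (class != unchanged) in the test contrast at the
    base cutoff that are also regulated in the reference contrast.  Tier 2:
    events regulated in the test contrast but unchanged in the reference,
    which must additionally pass the stricter |delta PSI| cutoff.  Output is
    sorted by |delta PSI| descending, ties broken by event_id.
    """
    a = records_test.set_index("event_id")
    b = records_reference.set_index("event_id")
    if set(a.index) != set(b.index):
        raise CoverageError("shortlist contrasts cover different event universes")
    rows = []
    for event_id, r in a.iterrows():
        if r["regulation_class"] == "unchanged":
            continue
        if abs(r["delta_psi"]) < base_cutoff:
            continue
        ref_changed = b.loc[event_id, "regulation_class"] != "unchanged"
        if ref_changed:
            rows.append((event_id, r["delta_psi"], "tier1"))
        elif abs(r["delta_psi"]) >= strict_cutoff:
            rows.append((event_id, r["delta_psi"], "tier2"))
    out = pd.DataFrame(rows, columns=["event_id", "delta_psi", "tier"])
    out["absd"] = out["delta_psi"].abs()
    out = out.sort_values(["absd", "event_id"], ascending=[False, True])
    return out.drop(columns="absd").reset_index(drop=True)


def inclusion_proportion_test(n_inclusion_up: int, n_total: int) -> tuple[float, float]:
    """One-sided Pearson chi-square test of a proportion against 0.5.

    Returns ``(chi2, p_one_sided)`` where the one-sided p is half the
    chi-square(1 df) tail when the observed proportion exceeds 0.5, and one
    minus that half otherwise (direction: enrichment of inclusion-up events).
    """
    if n_total < 1:
        raise SampleSizeError("n_total must be >= 1")
    if not 0 <= n_inclusion_up <= n_total:
        raise SampleSizeError("n_inclusion_up must be within [0, n_total]")
    expected = n_total / 2.0
    chi2 = (n_inclusion_up - expected) ** 2 / expected + (
        (n_total - n_inclusion_up) - expected
    ) ** 2 / expected
    half_tail = stats.chi2.sf(chi2, df=1) / 2.0
    if n_inclusion_up / n_total > 0.5:
        p = half_tail
    else:
        p = 1.0 - half_tail
    return float(chi2), float(p)


def summarize_event_types(events: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of the five alternative-splicing event types."""
    bad = set(events["event_type"]) - EVENT_TYPES
    if bad:
        raise FormatError(f"unknown event_type values: {sorted(bad)}")
    counts = {t: int((events["event_type"] == t).sum()) for t in sorted(EVENT_TYPES)}
    total = sum(counts.values())
    rows = [
        dict(event_type=t, count=c, fraction=(c / total if total else 0.0))
        for t, c in counts.items()
    ]
    return pd.DataFrame(rows)
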