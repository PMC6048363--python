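"""Motif scanning with exact p-values and RNA-map enrichment statistics.

An RNA map is a positional profile of a splicing factor's binding-motif
density around alternative exons, compared between exon response groups
(repressed / enhanced / unchanged).  The pipeline here is:

1. scan flanking sequences with a position weight matrix (PWM), reporting a
   log-odds score and an exact p-value per occurrence;
2. anchor occurrences to the alternative exon's splice sites (negative
   offsets = intronic, transcript orientation, strand-aware);
3. compare, in moving windows along the anchored axis, the fraction of exons
   carrying at least one occurrence between a response group and the
   unchanged reference group with one-sided Fisher's exact tests.

The exact occurrence p-value is the probability, under the background
model, that a random width-w word scores at least the observed log-odds
score.  It is computed by dynamic programming over a discretized score
distribution, refined adaptively until the survival function is stable.
Scanning is single-stranded on transcript-sense sequences (RNA-binding
motifs have no reverse-complement partner site).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CoverageError, ParameterError
from .enrichment import bh_fdr

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}


@dataclass
class Pwm:
    """Column-stochastic motif model over the canonical DNA alphabet.

    ``probabilities`` is 4 x width (rows A, C, G, T).  A pseudocount is mixed
    in before log-odds scoring: q = (p + pc) / (1 + 4 pc).
    """

    probabilities: np.ndarray
    pseudocount: float = 0.001
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[0] != 4:
            raise ParameterError("PWM must be a 4 x width matrix")
        if self.pseudocount <= 0:
            raise ParameterError("pseudocount must be > 0")
        if (self.background <= 0).any() or abs(self.background.sum() - 1) > 1e-9:
            raise ParameterError("background must be a strictly positive simplex")
        if np.abs(self.probabilities.sum(axis=0) - 1).max() > 1e-6:
            raise ParameterError("PWM columns must sum to 1")
        q = (self.probabilities + self.pseudocount) / (1 + 4 * self.pseudocount)
        self.log_odds = np.log2(q / self.background[:, None])
        self._sf_cache: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    # -- exact score distribution ------------------------------------------
    _EXACT_MAX_WIDTH = 10  # achievable sums bounded by 4^w; exact DP up to here
    _LATTICE_SCALE = float(2**40)

    def _lattice_distribution(self):
        """Exact score distribution on a 2^-40 lattice.

        Column scores are quantized to integers at 2^-40 granularity, so
        distinct word scores merge only when within ~5e-12 bits; the DP state
        is the set of achievable quantized sums (at most 4^w entries).
        """
        m = self._LATTICE_SCALE
        ints = np.rint(self.log_odds * m).astype(np.int64)
        sums = np.zeros(1, dtype=np.int64)
        probs = np.ones(1)
        for j in range(self.width):
            col = ints[:, j]
            ns = (sums[:, None] + col[None, :]).ravel()
            np_ = (probs[:, None] * self.background[None, :]).ravel()
            sums, inv = np.unique(ns, return_inverse=True)
            probs = np.bincount(inv, weights=np_)
        scores = sums / m
        tail = np.cumsum(probs[::-1])[::-1]
        fuzz = (self.width / 2 + 1) / m  # quantization + float accumulation slack
        return scores, tail, fuzz

    def _binned_distribution(self, nbins: int):
        """Distribution of the word score under the background model, with
        scores rounded to multiples of delta = score range / nbins."""
        lods = self.log_odds
        rng_total = lods.max(axis=0).sum() - lods.min(axis=0).sum()
        delta = max(rng_total, 1e-12) / nbins
        ints = np.rint(lods / delta).astype(np.int64)
        dist = np.array([1.0])
        base = 0
        for j in range(self.width):
            col = ints[:, j]
            lo = int(col.min())
            new = np.zeros(len(dist) + int(col.max()) - lo)
            for a in range(4):
                off = int(col[a]) - lo
                new[off:off + len(dist)] += self.background[a] * dist
            dist = new
            base += lo
        scores = (base + np.arange(len(dist))) * delta
        return scores, dist, delta

    def _survival(self):
        """Cached exact survival function of the word score.

        The bin count is doubled until the survival probabilities at a probe
        grid of scores are stable to 1e-7 relative (1e-12 absolute)."""
        if self._sf_cache is not None:
            return self._sf_cache
        if self.width <= self._EXACT_MAX_WIDTH:
            self._sf_cache = self._lattice_distribution()
            return self._sf_cache
        w = self.width
        nbins = 20_000
        prev = None
        cache = None
        for _ in range(6):
            scores, dist, delta = self._binned_distribution(nbins)
            tail = np.cumsum(dist[::-1])[::-1]
            # score rounding moves a word's score by at most w*delta/2
            fuzz = w * delta / 2 + 1e-12
            cache = (scores, tail, fuzz)
            probes = np.linspace(scores[0], scores[-1], 101)
            idx = np.searchsorted(scores, probes - fuzz, side="left")
            cur = np.where(idx < len(tail), tail[np.minimum(idx, len(tail) - 1)], 0.0)
            if prev is not None and np.max(np.abs(cur - prev)) <= 1e-8:
                break
            prev = cur
            nbins *= 2
        self._sf_cache = cache
        return self._sf_cache

    def score_pvalue(self, score) -> np.ndarray:
        """Exact p-value(s): P(random word score >= score) under background."""
        scores, tail, fuzz = self._survival()
        s = np.atleast_1d(np.asarray(score, dtype=float))
        idx = np.searchsorted(scores, s - fuzz, side="left")
        p = np.where(idx < len(tail), tail[np.minimum(idx, len(tail) - 1)], 0.0)
        return p if np.ndim(score) else float(p[0])


def cu_rich_example_pwm() -> Pwm:
    """A synthetic pyrimidine (CU)-rich example matrix for tests and demos.

    This is a stand-in constructed for this package, not a published
    RNAcompete matrix; it mimics the C/U-rich composition of PTBP1-type
    binding sites (UCUU core on the DNA alphabet).  Consensus: TCTTTCTT.
    """
    #                 T     C     T     T     T     C     T     T
    probs = np.array(
        [
            [0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02],  # A
            [0.08, 0.88, 0.08, 0.08, 0.08, 0.88, 0.08, 0.08],  # C
            [0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02],  # G
            [0.88, 0.08, 0.88, 0.88, 0.88, 0.08, 0.88, 0.88],  # T
        ]
    )
    return Pwm(probs)


def pwm_scan(
    sequence: str,
    pwm: Pwm,
    p_threshold: float = 1e-4,
    sequence_id: str = "seq",
) -> pd.DataFrame:
    """Scan a sequence (sense strand only) and report occurrences with
    p <= p_threshold.

    Positions containing ``N`` are skipped.  A sequence shorter than the
    motif yields an empty table.
    """
    w = pwm.width
    cols = ["sequence_id", "start", "end", "score", "p"]
    n = len(sequence)
    if n < w:
        return pd.DataFrame(columns=cols)
    code = np.array([_CODE.get(c, -1) for c in sequence], dtype=np.int64)
    n_off = n - w + 1
    scores = np.zeros(n_off)
    valid = np.ones(n_off, dtype=bool)
    for j in range(w):
        cj = code[j:j + n_off]
        valid &= cj >= 0
        scores += pwm.log_odds[np.clip(cj, 0, 3), j]
    pvals = np.asarray(pwm.score_pvalue(scores))
    keep = valid & (pvals <= p_threshold)
    starts = np.where(keep)[0]
    return pd.DataFrame(
        {
            "sequence_id": sequence_id,
            "start": starts,
            "end": starts + w,
            "score": scores[keep],
            "p": pvals[keep],
        },
        columns=cols,
    )


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """Extents of the scanned regions around the alternative exon (nt)."""

    upstream_flank: int = 300
    exon_window: int = 50
    downstream_flank: int = 300


def _transcript_offsets(event, g_start: int, g_end: int, anchor: str):
    """Offsets of genomic interval [g_start, g_end) relative to a splice site
    of the alternative exon, in transcript orientation.

    ``anchor='acceptor'`` (3' splice site): offset 0 is the first exonic nt,
    negative offsets run into the upstream intron.  ``anchor='donor'``
    (5' splice site): offset 0 is the first intronic nt downstream, negative
    offsets run back into the exon.
    """
    a0, a1 = int(event["alt_start"]), int(event["alt_end"])
    strand = event["strand"]
    if anchor == "acceptor":
        if strand == "+":
            return g_start - a0, g_end - a0
        return a1 - g_end, a1 - g_start
    if anchor == "donor":
        if strand == "+":
            return g_start - a1, g_end - a1
        return a0 - g_end, a0 - g_start
    raise ParameterError(f"unknown anchor {anchor!r}")


def anchor_occurrences(
    event,
    occurrences: pd.DataFrame,
    region_spec: RegionSpec = RegionSpec(),
) -> tuple[pd.DataFrame, int]:
    """Anchor genomic motif occurrences of one event to its splice sites.

    ``occurrences`` carries genomic ``start``/``end`` (0-based half-open) on
    the event's chromosome.  An occurrence is assigned to the acceptor axis
    if it lies fully within [-upstream_flank, exon_window), else to the donor
    axis within [-exon_window, downstream_flank); occurrences outside both
    are dropped and counted.

    Returns (anchored table with columns event_id, anchor, offset_start,
    offset_end, plus a copy of score/p if present; dropped count).
    """
    rows = []
    dropped = 0
    for _, occ in occurrences.iterrows():
        s, e = int(occ["start"]), int(occ["end"])
        placed = False
        for anchor, lo, hi in (
            ("acceptor", -region_spec.upstream_flank, region_spec.exon_window),
            ("donor", -region_spec.exon_window, region_spec.downstream_flank),
        ):
            o_start, o_end = _transcript_offsets(event, s, e, anchor)
            if o_start >= lo and o_end <= hi:
                rows.append(
                    dict(
                        event_id=event["event_id"], anchor=anchor,
                        offset_start=o_start, offset_end=o_end,
                        score=occ.get("score", np.nan), p=occ.get("p", np.nan),
                    )
                )
                placed = True
                break
        if not placed:
            dropped += 1
    cols = ["event_id", "anchor", "offset_start", "offset_end", "score", "p"]
    return pd.DataFrame(rows, columns=cols), dropped


def local_to_genomic(event, region: str, start: int, end: int, flank_len: int):
    """Map an occurrence on an extracted flank sequence (transcript
    orientation, local coordinates) to genomic coordinates.

    ``region`` is one of ``upstream_intron`` (flank of length ``flank_len``
    ending at the 3' splice site), ``exon`` (the whole alternative exon) or
    ``downstream_intron`` (flank starting at the 5' splice site).
    """
    a0, a1 = int(event["alt_start"]), int(event["alt_end"])
    plus = event["strand"] == "+"
    if region == "upstream_intron":
        if plus:
            return a0 - flank_len + start, a0 - flank_len + end
        return a1 + flank_len - end, a1 + flank_len - start
    if region == "exon":
        if plus:
            return a0 + start, a0 + end
        return a1 - end, a1 - start
    if region == "downstream_intron":
        if plus:
            return a1 + start, a1 + end
        return a0 - end, a0 - start
    raise ParameterError(f"unknown region {region!r}")


# ---------------------------------------------------------------------------
# RNA map
# ---------------------------------------------------------------------------

@dataclass
class RnaMapResult:
    anchor: str
    offsets: np.ndarray
    densities: dict[str, np.ndarray]
    group_sizes: dict[str, int]
    windows: pd.DataFrame  # center, group, table counts, odds_ratio, p


def build_rna_map(
    groups: dict[str, str],
    anchored: pd.DataFrame,
    window: int = 31,
    step: int = 1,
    region_spec: RegionSpec = RegionSpec(),
    anchor: str = "acceptor",
    reference_group: str = "unchanged",
    alternative: str = "greater",
) -> RnaMapResult:
    """Positional motif densities per response group and moving-window
    Fisher enrichment tests against the unchanged reference group.

    ``groups`` maps event_id -> class; ``anchored`` is the output of
    :func:`anchor_occurrences` pooled over events.  The Fisher unit is the
    exon: the 2x2 table counts exons with and without at least one occurrence
    overlapping the window, in the test group versus the reference group.
    One-sided (enrichment) by default.
    """
    if anchor == "acceptor":
        lo, hi = -region_spec.upstream_flank, region_spec.exon_window
    else:
        lo, hi = -region_spec.exon_window, region_spec.downstream_flank
    axis = np.arange(lo, hi)
    n_pos = len(axis)

    group_names = sorted(set(groups.values()))
    if reference_group not in group_names:
        raise CoverageError(f"reference group {reference_group!r} is empty")
    events_by_group = {g: [e for e, c in groups.items() if c == g] for g in group_names}

    occ = anchored[anchored["anchor"] == anchor]
    occ_by_event: dict[str, list[tuple[int, int]]] = {}
    for _, r in occ.iterrows():
        occ_by_event.setdefault(r["event_id"], []).append(
            (int(r["offset_start"]), int(r["offset_end"]))
        )

    half = window // 2
    centers = axis[(axis - half >= lo) & (axis + half < hi)][::step]

    densities = {}
    win_pos_counts = {}
    for g, events in events_by_group.items():
        dens = np.zeros(n_pos)
        win_mark = np.zeros((len(events), len(centers)), dtype=bool)
        for i, ev in enumerate(events):
            cover = np.zeros(n_pos, dtype=bool)
            for (s, e) in occ_by_event.get(ev, []):
                cover[max(s - lo, 0):max(e - lo, 0)] = True
                # centers whose window [c-half, c+half] intersects [s, e)
                c_lo = np.searchsorted(centers, s - half)
                c_hi = np.searchsorted(centers, e - 1 + half, side="right")
                win_mark[i, c_lo:c_hi] = True
            dens += cover
        densities[g] = dens / max(len(events), 1)
        win_pos_counts[g] = win_mark.sum(axis=0)

    n_ref = len(events_by_group[reference_group])
    ref_pos = win_pos_counts[reference_group]
    rows = []
    for g in group_names:
        if g == reference_group:
            continue
        n_test = len(events_by_group[g])
        a = win_pos_counts[g].astype(float)
        c = ref_pos.astype(float)
        if alternative == "greater":
            # one-sided enrichment: hypergeometric tail P(X >= a)
            p = stats.hypergeom.sf(a - 1, n_test + n_ref, a + c, n_test)
        else:
            p = np.array(
                [
                    stats.fisher_exact(
                        [[ai, n_test - ai], [ci, n_ref - ci]], alternative="two-sided"
                    )[1]
                    for ai, ci in zip(a, c)
                ]
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * (n_ref - c)) / ((n_test - a) * c)
        for ci, center in enumerate(centers):
            rows.append(
                dict(
                    center=int(center), group=g,
                    n_test_pos=int(a[ci]), n_test=n_test,
                    n_ref_pos=int(c[ci]), n_ref=n_ref,
                    odds_ratio=float(odds[ci]), p=float(p[ci]),
                )
            )
    windows = pd.DataFrame(
        rows,
        columns=["center", "group", "n_test_pos", "n_test",
                 "n_ref_pos", "n_ref", "odds_ratio", "p"],
    )
    return RnaMapResult(
        anchor=anchor, offsets=axis, densities=densities,
        group_sizes={g: len(v) for g, v in events_by_group.items()},
        windows=windows,
    )


def window_significance(windows: pd.DataFrame, adjust: bool = False) -> pd.DataFrame:
    """Annotate window tests; raw p as the headline statistic, with an
    optional Benjamini-Hochberg column (off by default)."""
    out = windows.copy()
    if adjust and len(out):
        out["p_adj"] = np.nan
        for g, idx in out.groupby("group").groups.items():
            out.loc[idx, "p_adj"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out
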