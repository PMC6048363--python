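"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* :func:`simulate_screen` — 96-well siRNA screen plates with additive
  row/column artifacts, scramble negative controls, inhibitor positive
  controls and planted gene effects (in units of the within-plate noise SD).
* :func:`simulate_splicing` — cassette-exon junction counts drawn binomially
  from true inclusion levels, with knockdown-repressed events carrying a
  pyrimidine-rich motif embedded upstream of their 3' splice site.
* :func:`simulate_tissue_matrix` — a gene-by-sample count matrix in which a
  bimodal regulator anti-correlates with a bimodal exon-PSI vector and one
  planted gene set is up-shifted in the high-skipping samples.

All generators are deterministic under a fixed seed; a single global seed
fans out to independent per-simulator substreams via
:func:`numpy.random.SeedSequence` spawning (see :func:`substreams`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CapacityError, ParameterError
from .io_formats import GeneSet

PLATE_ROWS = 8
PLATE_COLS = 12
SAMPLE_WELLS_PER_PLATE = PLATE_ROWS * (PLATE_COLS - 1)  # column 12 is controls
SCREEN_READOUTS = ("IL8", "IL6", "p16", "p21", "BrdU")


def substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a global seed out into ``n`` independent generator substreams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# screen simulator
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimTruth:
    effects: pd.DataFrame          # gene x readout, in units of noise SD
    down_hits: list[str]
    up_hits: list[str]
    layout: pd.DataFrame           # gene -> plate_id, row, col
    row_artifacts: dict            # (plate_id, replicate) -> per-row shifts
    col_artifacts: dict            # (plate_id, replicate) -> per-col shifts
    noise_sd: float
    baseline: float


def simulate_screen(
    n_genes: int,
    n_plates: int | None = None,
    replicate_count: int = 3,
    effect_table: pd.DataFrame | None = None,
    row_artifact_sd: float = 0.5,
    col_artifact_sd: float = 0.5,
    noise_sd: float = 1.0,
    baseline: float = 50.0,
    pos_control_effect: float = -6.0,
    readouts: tuple[str, ...] = SCREEN_READOUTS,
    seed: int = 0,
) -> tuple[pd.DataFrame, ScreenSimTruth]:
    """Simulate a plate-based siRNA screen.

    Each 96-well plate has 88 sample wells (columns 1-11) and 8 control
    wells in column 12 (rows 1-4 scramble negative controls, rows 5-8
    positive inhibitor controls).  A well's value is

        baseline + row artifact + column artifact
                 + gene effect * noise_sd (sample wells only)
                 + Gaussian noise (sd = noise_sd),

    with row/column artifacts drawn independently per plate and replicate.
    ``effect_table`` is a gene x readout table of effect sizes in noise-SD
    units (default: all zero); positive controls carry
    ``pos_control_effect`` on IL8/IL6 only.
    """
    if n_plates is None:
        n_plates = max(1, -(-n_genes // SAMPLE_WELLS_PER_PLATE))
    if n_genes > n_plates * SAMPLE_WELLS_PER_PLATE:
        raise CapacityError(
            f"{n_genes} siRNAs exceed {n_plates} plates x "
            f"{SAMPLE_WELLS_PER_PLATE} sample wells"
        )
    genes = [f"GENE{g:06d}" for g in range(n_genes)]
    if effect_table is None:
        effect_table = pd.DataFrame(0.0, index=genes, columns=list(readouts))
    else:
        effect_table = effect_table.reindex(index=genes, columns=list(readouts),
                                            fill_value=0.0).astype(float)

    rng = np.random.default_rng(seed)
    rows_all, layout_rows = [], []
    row_art, col_art = {}, {}

    # fixed layout: gene g sits at plate g // 88, sample-well slot g % 88
    for g, gene in enumerate(genes):
        p = g // SAMPLE_WELLS_PER_PLATE
        slot = g % SAMPLE_WELLS_PER_PLATE
        layout_rows.append(
            dict(gene_id=gene, plate_id=f"P{p + 1:04d}",
                 row=slot % PLATE_ROWS + 1, col=slot // PLATE_ROWS + 1)
        )
    layout = pd.DataFrame(layout_rows)
    by_plate = layout.groupby("plate_id", sort=True)

    cyto = [r for r in ("IL8", "IL6") if r in readouts]
    for p in range(n_plates):
        plate_id = f"P{p + 1:04d}"
        plate_genes = (
            by_plate.get_group(plate_id) if plate_id in by_plate.groups else None
        )
        for rep in range(1, replicate_count + 1):
            re_ = rng.normal(0, row_artifact_sd, PLATE_ROWS)
            ce_ = rng.normal(0, col_artifact_sd, PLATE_COLS)
            row_art[(plate_id, rep)] = re_
            col_art[(plate_id, rep)] = ce_
            noise = rng.normal(0, noise_sd, (PLATE_ROWS, PLATE_COLS, len(readouts)))
            # well bookkeeping
            well_gene = {}
            if plate_genes is not None:
                for _, lr in plate_genes.iterrows():
                    well_gene[(lr["row"], lr["col"])] = lr["gene_id"]
            for r in range(1, PLATE_ROWS + 1):
                for c in range(1, PLATE_COLS + 1):
                    if c == PLATE_COLS:
                        role = "negative_control" if r <= 4 else "positive_control"
                        gene_id = "scramble" if r <= 4 else "pos_ctrl"
                        sirna = f"{gene_id}_{plate_id}_{r}"
                    elif (r, c) in well_gene:
                        role, gene_id = "sample", well_gene[(r, c)]
                        sirna = f"si_{gene_id}"
                    else:
                        role, gene_id, sirna = "empty", "", ""
                    rec = dict(plate_id=plate_id, replicate=rep, row=r, col=c,
                               well_role=role, sirna_id=sirna, gene_id=gene_id)
                    for k, readout in enumerate(readouts):
                        if role == "empty":
                            rec[readout] = np.nan
                            continue
                        eff = 0.0
                        if role == "sample":
                            eff = effect_table.at[gene_id, readout]
                        elif role == "positive_control" and readout in cyto:
                            eff = pos_control_effect
                        rec[readout] = (
                            baseline + re_[r - 1] + ce_[c - 1]
                            + eff * noise_sd + noise[r - 1, c - 1, k]
                        )
                    rows_all.append(rec)

    plates = pd.DataFrame(rows_all)
    down = effect_table.index[(effect_table[cyto] < 0).all(axis=1)
                              & (effect_table[cyto] != 0).any(axis=1)].tolist()
    up = effect_table.index[(effect_table[cyto] > 0).all(axis=1)].tolist()
    truth = ScreenSimTruth(
        effects=effect_table, down_hits=down, up_hits=up, layout=layout,
        row_artifacts=row_art, col_artifacts=col_art,
        noise_sd=noise_sd, baseline=baseline,
    )
    return plates, truth


# ---------------------------------------------------------------------------
# splicing simulator
# ---------------------------------------------------------------------------

@dataclass
class SpliceSimTruth:
    events: pd.DataFrame   # event_id, regulation_class, psi_control, psi_knockdown,
                           # motif_offset (relative to the 3' splice site; NaN if none)
    motif: str
    placement_window: tuple[int, int]
    coverage: int


DEFAULT_MOTIF = "TCTTTCTT"  # consensus of the CU-rich example matrix


def simulate_splicing(
    n_events: int = 400,
    class_proportions: dict[str, float] | None = None,
    coverage: int = 100,
    delta_psi: float = 0.3,
    flank_len: int = 300,
    exon_len: int = 120,
    motif: str = DEFAULT_MOTIF,
    placement_window: tuple[int, int] = (-60, -20),
    n_replicates: int = 3,
    conditions: tuple[str, str] = ("control", "knockdown"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], SpliceSimTruth]:
    """Simulate cassette-exon events with junction counts and flank sequences.

    Per event and sample, the two inclusion junctions and the skipping
    junction are drawn ``Binomial(coverage, psi)`` and
    ``Binomial(coverage, 1 - psi)`` respectively.  Repressed events have
    ``psi(knockdown) = psi(control) + delta_psi`` (inclusion rises when the
    repressor is depleted) and carry one embedded motif instance inside
    ``placement_window`` (offsets relative to the 3' splice site, negative =
    upstream intron); enhanced events mirror the PSI change without a motif;
    unchanged events carry background-only sequence.

    Returns ``(event table, junction counts, flank sequences keyed
    '<event>|<region>', truth)``.
    """
    props = class_proportions or {"repressed": 0.15, "enhanced": 0.1, "unchanged": 0.75}
    if abs(sum(props.values()) - 1) > 1e-9:
        raise ParameterError("class proportions must sum to 1")
    if not 0 <= delta_psi <= 0.9:
        raise ParameterError("delta_psi must lie in [0, 0.9]")
    w0, w1 = placement_window
    if not -flank_len <= w0 < w1 <= 0:
        raise ParameterError("placement_window must lie within the upstream flank")
    if len(motif) > w1 - w0:
        raise ParameterError("motif longer than the placement window")

    rng = np.random.default_rng(seed)
    classes = rng.choice(
        list(props.keys()), size=n_events, p=list(props.values())
    )
    margin = 0.05
    event_rows, truth_rows, junc_rows = [], [], []
    flanks: dict[str, str] = {}
    bases = np.array(list("ACGT"))

    for i in range(n_events):
        event_id = f"EV{i:05d}"
        cls = classes[i]
        if cls == "repressed":
            psi_c = rng.uniform(margin, 1 - delta_psi - margin)
            psi_k = psi_c + delta_psi
        elif cls == "enhanced":
            psi_c = rng.uniform(delta_psi + margin, 1 - margin)
            psi_k = psi_c - delta_psi
        else:
            psi_c = rng.uniform(margin, 1 - margin)
            psi_k = psi_c
        strand = "+" if i % 2 == 0 else "-"
        base = 100_000 + i * 10_000
        event_rows.append(
            dict(event_id=event_id, event_type="SE", chrom="chr1", strand=strand,
                 exon1_start=base, exon1_end=base + 150,
                 alt_start=base + 150 + 1_000, alt_end=base + 150 + 1_000 + exon_len,
                 exon2_start=base + 150 + 1_000 + exon_len + 1_000,
                 exon2_end=base + 150 + 1_000 + exon_len + 1_000 + 150)
        )

        for cond, psi in zip(conditions, (psi_c, psi_k)):
            for rep in range(1, n_replicates + 1):
                inc1, inc2 = rng.binomial(coverage, psi, size=2)
                skip = rng.binomial(coverage, 1 - psi)
                junc_rows.append(
                    dict(event_id=event_id, sample_id=f"{cond}_{rep}",
                         condition=cond, inc1=int(inc1), inc2=int(inc2),
                         skip=int(skip))
                )

        up = "".join(rng.choice(bases, flank_len))
        exon = "".join(rng.choice(bases, exon_len))
        down = "".join(rng.choice(bases, flank_len))
        motif_offset = np.nan
        if cls == "repressed":
            # embed one motif instance inside the placement window
            off = int(rng.integers(w0, w1 - len(motif) + 1))
            local = off + flank_len  # offset -flank_len maps to local 0
            up = up[:local] + motif + up[local + len(motif):]
            motif_offset = off
        flanks[f"{event_id}|upstream_intron"] = up
        flanks[f"{event_id}|exon"] = exon
        flanks[f"{event_id}|downstream_intron"] = down
        truth_rows.append(
            dict(event_id=event_id, regulation_class=cls,
                 psi_control=psi_c, psi_knockdown=psi_k,
                 motif_offset=motif_offset)
        )

    events = pd.DataFrame(event_rows)
    junctions = pd.DataFrame(junc_rows)
    truth = SpliceSimTruth(
        events=pd.DataFrame(truth_rows), motif=motif,
        placement_window=placement_window, coverage=coverage,
    )
    return events, junctions, flanks, truth


# ---------------------------------------------------------------------------
# tissue simulator
# ---------------------------------------------------------------------------

@dataclass
class TissueSimTruth:
    enriched_set: GeneSet
    regulator_gene: str
    sample_high_regulator: pd.Series  # bool per sample
    psi_true: pd.Series
    set_effect: float = 1.0


def simulate_tissue_matrix(
    n_genes: int = 4000,
    n_samples: int = 300,
    regulator_modes: tuple[tuple[float, float], tuple[float, float]] = ((6.0, 0.3), (9.0, 0.3)),
    psi_modes: tuple[tuple[float, float], tuple[float, float]] = ((0.2, 0.05), (0.8, 0.05)),
    enriched_set_size: int = 30,
    set_effect: float = 1.0,
    mean_library_size: float = 2e6,
    dispersion: float = 0.1,
    regulator_gene: str = "PTBP1",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, TissueSimTruth]:
    """Simulate a cross-tissue count matrix with a bimodal regulator.

    Half of the samples are regulator-high (log2 expression from the second
    regulator mode); exon inclusion (PSI) is drawn from the low-inclusion
    mode in those samples and from the high-inclusion mode otherwise, making
    the sample-level regulator/PSI correlation negative by construction.
    Genes of the planted enriched set are up-shifted by ``set_effect`` log2
    units in the high-skipping (regulator-high) samples.  Counts are
    negative-binomial (Gamma-Poisson with the given dispersion, i.e.
    biological coefficient of variation ~ sqrt(dispersion)) around log-normal
    gene baselines scaled by per-sample library factors.
    """
    if mean_library_size <= 0:
        raise ParameterError("library size must be positive")
    if enriched_set_size > n_genes - 1:
        raise ParameterError("enriched set larger than the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes - 1)] + [regulator_gene]
    samples = [f"S{i:04d}" for i in range(n_samples)]

    high = rng.random(n_samples) < 0.5
    (rm_lo, rs_lo), (rm_hi, rs_hi) = regulator_modes
    reg_log = np.where(high, rng.normal(rm_hi, rs_hi, n_samples),
                       rng.normal(rm_lo, rs_lo, n_samples))
    (pm_lo, ps_lo), (pm_hi, ps_hi) = psi_modes
    psi = np.where(high, rng.normal(pm_lo, ps_lo, n_samples),
                   rng.normal(pm_hi, ps_hi, n_samples))
    psi = np.clip(psi, 0.0, 1.0)

    set_genes = list(rng.choice(genes[:-1], size=enriched_set_size, replace=False))

    base_log = rng.normal(5.0, 1.2, n_genes)
    log_mu = np.tile(base_log[:, None], (1, n_samples))
    log_mu[genes.index(regulator_gene), :] = reg_log
    set_idx = [genes.index(g) for g in set_genes]
    log_mu[np.ix_(set_idx, np.where(high)[0])] += set_effect

    lib_factor = np.exp(rng.normal(0, 0.1, n_samples))
    mu = 2.0 ** log_mu * (mean_library_size / 2.0**base_log.mean() / n_genes)
    mu = mu * lib_factor[None, :]
    if dispersion > 0:
        # Gamma-Poisson mixture = negative binomial with the given dispersion
        mu = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    counts = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    psi_s = pd.Series(psi, index=samples, name="psi")
    truth = TissueSimTruth(
        enriched_set=GeneSet("PLANTED_SET", "simulated enriched set", set_genes),
        regulator_gene=regulator_gene,
        sample_high_regulator=pd.Series(high, index=samples),
        psi_true=psi_s.copy(),
        set_effect=set_effect,
    )
    return counts_df, psi_s, truth


def decoy_gene_sets(
    genes: list[str],
    exclude: list[str],
    n_sets: int = 50,
    size: int = 30,
    seed: int = 0,
) -> list[GeneSet]:
    """Random gene sets drawn from the universe (minus ``exclude``) to serve
    as unenriched competitors in FDR evaluations."""
    rng = np.random.default_rng(seed)
    pool = [g for g in genes if g not in set(exclude)]
    if size > len(pool):
        raise ParameterError("decoy size exceeds the available gene pool")
    return [
        GeneSet(f"DECOY{i:03d}", "random decoy set",
                list(rng.choice(pool, size=size, replace=False)))
        for i in range(n_sets)
    ]
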