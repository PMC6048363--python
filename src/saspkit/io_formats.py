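"""Readers and writers for the tabular and sequence formats the pipeline touches.

Conventions
-----------
* All genomic coordinates are 0-based half-open internally and on disk
  (BED convention).
* Sequences are canonicalized to the DNA alphabet: upper case, ``U`` mapped
  to ``T``.  Motif matrices are defined over the same alphabet.
* Tables are plain delimited text with a header row and a stable column
  order, read into :class:`pandas.DataFrame`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import ConfigError, FormatError

log = logging.getLogger("saspkit")

PLATE_KEY_COLUMNS = [
    "plate_id",
    "replicate",
    "row",
    "col",
    "well_role",
    "sirna_id",
    "gene_id",
]
WELL_ROLES = {"sample", "negative_control", "positive_control", "empty"}

EVENT_COLUMNS = [
    "event_id",
    "event_type",
    "chrom",
    "strand",
    "exon1_start",
    "exon1_end",
    "alt_start",
    "alt_end",
    "exon2_start",
    "exon2_end",
]
EVENT_TYPES = {"SE", "RI", "MXE", "A5SS", "A3SS"}

_COORD_COLS = [
    "exon1_start",
    "exon1_end",
    "alt_start",
    "alt_end",
    "exon2_start",
    "exon2_end",
]

VALID_BASES = set("ACGTN")


@dataclass
class GeneSet:
    """A named gene set (one GMT line)."""

    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = list(dict.fromkeys(self.genes))  # unique, order kept

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# plate tables
# ---------------------------------------------------------------------------

def validate_plate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format plate table; returns the table with readout
    columns coerced to float.

    Raises :class:`FormatError` on missing columns, unknown well roles or
    duplicate (plate, replicate, row, col) keys, naming the offending well.
    """
    missing = [c for c in PLATE_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"plate table missing required columns: {missing}")
    bad_roles = set(df["well_role"]) - WELL_ROLES
    if bad_roles:
        raise FormatError(f"unknown well_role values: {sorted(bad_roles)}")
    key = ["plate_id", "replicate", "row", "col"]
    dup = df[df.duplicated(key, keep=False)]
    if not dup.empty:
        r = dup.iloc[0]
        raise FormatError(
            f"duplicate well: plate {r['plate_id']} replicate {r['replicate']} "
            f"row {r['row']} col {r['col']}"
        )
    readouts = readout_columns(df)
    if not readouts:
        raise FormatError("plate table has no readout columns")
    out = df.copy()
    for c in readouts:
        out[c] = pd.to_numeric(out[c], errors="raise")
    return out


def readout_columns(df: pd.DataFrame) -> list[str]:
    """Names of the readout (measurement) columns of a plate table."""
    return [c for c in df.columns if c not in PLATE_KEY_COLUMNS]


def read_plate_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a delimited plate table (one row per well)."""
    df = pd.read_csv(path, sep=sep)
    return validate_plate_table(df)


def write_plate_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    cols = PLATE_KEY_COLUMNS + readout_columns(df)
    df.to_csv(path, sep=sep, index=False, columns=cols)


# ---------------------------------------------------------------------------
# event tables (BED-derived, 0-based half-open)
# ---------------------------------------------------------------------------

def validate_event_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event table missing required columns: {missing}")
    bad = set(df["event_type"]) - EVENT_TYPES
    if bad:
        raise FormatError(f"unknown event_type values: {sorted(bad)}")
    bad_strand = set(df["strand"]) - {"+", "-"}
    if bad_strand:
        raise FormatError(f"strand must be '+' or '-', got {sorted(bad_strand)}")
    for _, r in df.iterrows():
        coords = [int(r[c]) for c in _COORD_COLS]
        for (s, e), name in zip(zip(coords[::2], coords[1::2]),
                                ("exon1", "alt", "exon2")):
            if s >= e:
                raise FormatError(
                    f"event {r['event_id']}: {name} interval start >= end ({s} >= {e})"
                )
        # ordered, non-overlapping along the genomic axis
        if not (coords[1] <= coords[2] and coords[3] <= coords[4]):
            raise FormatError(
                f"event {r['event_id']}: intervals overlap or are out of genomic order"
            )
    return df


def read_events_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-derived event table (tab-separated, documented column order)."""
    df = pd.read_csv(path, sep="\t")
    return validate_event_table(df)


def write_events_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def canonicalize_sequence(seq: str, name: str = "?") -> str:
    """Upper-case and map RNA ``U`` to DNA ``T``; reject foreign characters."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise FormatError(f"sequence {name}: invalid characters {sorted(bad)}")
    return s


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{name: sequence}`` mapping (canonical DNA)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA record id {rec.id}")
        out[rec.id] = canonicalize_sequence(str(rec.seq), rec.id)
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {i}: GMT line needs >=3 fields")
            name, desc, genes = parts[0], parts[1], parts[2:]
            if name in seen:
                raise FormatError(f"{path}: line {i}: duplicate set name {name}")
            seen.add(name)
            sets.append(GeneSet(name, desc, [g for g in genes if g]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# count matrices and generic result tables
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample count matrix; first column is the gene id index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id in count matrix: {dup}")
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def write_results_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with stable column order (as provided)."""
    df.to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "saspkit_run",
    "screen_sim": {
        "n_genes": 352,
        "replicate_count": 3,
        "noise_sd": 1.0,
        "row_artifact_sd": 0.5,
        "col_artifact_sd": 0.5,
        "n_down_hits": 12,
        "n_up_hits": 4,
        "down_effect": -4.0,
        "up_effect": 4.0,
    },
    "splice_sim": {
        "n_events": 400,
        "coverage": 100,
        "delta_psi": 0.3,
        "flank_len": 300,
        "exon_len": 120,
        "n_replicates": 3,
        "prop_repressed": 0.15,
        "prop_enhanced": 0.1,
    },
    "tissue_sim": {
        "n_genes": 4000,
        "n_samples": 300,
        "enriched_set_size": 30,
    },
    "plate_stats": {"mad_constant": 1.4826, "max_iter": 100, "tol": 1e-6},
    "screen_calls": {
        "down_cutoff": -2.0,
        "up_cutoff": 2.0,
        "min_replicates": 2,
        "n_replicates": 3,
        "as_printed": False,
        "npi_cutoff": 0.8,
        "alpha": 0.05,
        "min_sirnas": 2,
        "k": 4,
        "n_init": 10,
        "reversion_margin": 2.0,
    },
    "splicing": {"delta_cutoff": 0.2, "strict_cutoff": 0.3, "fdr_cutoff": 0.05},
    "rna_map": {
        "window": 31,
        "step": 1,
        "upstream_flank": 300,
        "exon_window": 50,
        "downstream_flank": 300,
        "p_threshold": 1e-4,
    },
    "gsea": {"weight_exponent": 1.0, "n_perm": 1000},
    "cross_tissue": {"cpm_threshold": 10.0, "grid_points": 512},
}


def _check_keys(user: Mapping, defaults: Mapping, prefix: str = "") -> None:
    for k, v in user.items():
        if k not in defaults:
            raise ConfigError(f"unknown config key: {prefix}{k}")
        if isinstance(defaults[k], dict):
            if not isinstance(v, Mapping):
                raise ConfigError(f"config key {prefix}{k} must be a mapping")
            _check_keys(v, defaults[k], prefix=f"{prefix}{k}.")


def _merge(user: Mapping, defaults: Mapping) -> dict:
    out = {}
    for k, dv in defaults.items():
        if isinstance(dv, dict):
            out[k] = _merge(user.get(k, {}), dv)
        else:
            out[k] = user.get(k, dv)
    return out


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with validated keys.

    Unknown keys are rejected; every parameter is echoed to the log at run
    start so a run is fully reconstructible from its log.
    """

    values: dict = field(default_factory=lambda: _merge({}, DEFAULT_CONFIG))

    @classmethod
    def from_dict(cls, user: Mapping) -> "RunConfig":
        _check_keys(user, DEFAULT_CONFIG)
        return cls(_merge(user, DEFAULT_CONFIG))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        return cls.from_dict(user)

    def __getitem__(self, key: str):
        return self.values[key]

    def override(self, dotted_key: str, value) -> None:
        """Set ``section.key`` (CLI flags override file values)."""
        parts = dotted_key.split(".")
        node = self.values
        ref = DEFAULT_CONFIG
        for p in parts[:-1]:
            if p not in ref:
                raise ConfigError(f"unknown config key: {dotted_key}")
            node, ref = node[p], ref[p]
        if parts[-1] not in ref:
            raise ConfigError(f"unknown config key: {dotted_key}")
        node[parts[-1]] = value

    def log_all(self) -> None:
        def walk(d, prefix=""):
            for k, v in d.items():
                if isinstance(v, dict):
                    walk(v, prefix + k + ".")
                else:
                    log.info("config %s%s = %r", prefix, k, v)

        walk(self.values)
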