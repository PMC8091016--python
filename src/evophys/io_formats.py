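"""Readers and writers for the tabular formats shared by the analysis modules.

Canonical dialects
------------------
* Plate table: delimited text (comma or tab), header ``time,<well>,<well>,...``;
  the first column is time, remaining columns are OD readings per well.  Time
  is converted to hours internally.
* Plate layout: TSV with columns ``well, strain, carbon_source, replicate,
  role`` (role is ``sample`` or ``blank``), or a YAML mapping well -> fields.
* Chemostat records: TSV with columns ``substrate, D, S_in, S_res, X,
  ethanol, acetate, formate, lactate, pyruvate, malate, biomass_TOC``.
* Variant tables: TSV with columns ``contig, pos, ref, alt, type, isolate,
  frequency, depth``; a minimal VCF reader (CHROM/POS/REF/ALT + AF/DP in
  INFO) is provided for convenience.
* Gene models: TSV (``gene, contig, start, end, strand, product``) or a GFF3
  subset restricted to CDS features.
* Genomes: FASTA (via Biopython).

Result reports are TSV with fixed column orders; floats are written at full
precision alongside a rounded display column (two decimals for rates, one
decimal for lag hours), and NA fields are written as empty strings.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PlateTable",
    "PlateLayout",
    "WellAssignment",
    "ChemostatRecord",
    "VariantRecord",
    "GeneModel",
    "ParseError",
    "read_plate_table",
    "write_plate_table",
    "read_layout",
    "write_layout",
    "read_chemostat_table",
    "write_chemostat_table",
    "read_variant_table",
    "write_variant_table",
    "read_vcf",
    "read_gene_models",
    "write_gene_models",
    "read_fasta",
    "write_fasta",
    "write_results",
    "read_results",
]

#: Valid well identifiers on a 96-well plate (A1..H12, no zero padding).
WELL_ID_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")

_TIME_DIVISOR = {"seconds": 3600.0, "minutes": 60.0, "hours": 1.0}

#: Chemostat product columns, in report order.
PRODUCT_COLUMNS = ("ethanol", "acetate", "formate", "lactate", "pyruvate", "malate")


class ParseError(ValueError):
    """Raised when an input file violates the documented dialect."""


# ---------------------------------------------------------------------------
# Plate tables
# ---------------------------------------------------------------------------


@dataclass
class PlateTable:
    """Wide-format plate-reader table: a shared time axis and one OD series per well.

    ``times`` are hours and strictly increasing; ``readings`` is indexed
    positionally in step with ``times`` and has one column per well.  Missing
    OD cells are NaN and are masked per well downstream rather than dropping
    the time point plate-wide.
    """

    times: np.ndarray
    readings: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ParseError("no readings: empty time axis")
        if len(self.readings) != len(self.times):
            raise ParseError("time axis and readings have different lengths")
        diffs = np.diff(self.times)
        if np.any(diffs == 0):
            raise ParseError("duplicate timestamps in plate table")
        if np.any(diffs < 0):
            raise ParseError("non-monotone time axis")
        for well in self.readings.columns:
            if not WELL_ID_RE.match(str(well)):
                raise ParseError(f"invalid well id {well!r} for a 96-well plate")
            col = self.readings[well].to_numpy(dtype=float)
            bad = np.isinf(col) | (col < 0)
            if np.any(bad & ~np.isnan(col)):
                raise ParseError(f"negative or non-finite OD reading in well {well}")

    @property
    def wells(self) -> list[str]:
        return list(self.readings.columns)

    def series(self, well: str) -> np.ndarray:
        return self.readings[well].to_numpy(dtype=float)


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_plate_table(path, time_unit: str = "hours") -> PlateTable:
    """Read a wide-format plate table; times are converted to hours.

    Rows are sorted by time; duplicate timestamps and non-numeric OD cells are
    rejected with an error naming the offending row/column.
    """
    path = Path(path)
    if time_unit not in _TIME_DIVISOR:
        raise ValueError(f"time_unit must be one of {sorted(_TIME_DIVISOR)}")
    # round_trip parsing keeps written floats bit-identical on re-read
    raw = pd.read_csv(path, sep=_detect_sep(path), float_precision="round_trip")
    if raw.shape[0] == 0 or raw.shape[1] < 2:
        raise ParseError(f"no readings in {path}")
    time_col = raw.columns[0]
    data = {}
    for col in raw.columns:
        if pd.api.types.is_numeric_dtype(raw[col]):
            continue
        bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna() \
            & (raw[col].astype(str).str.strip() != "")
        row = int(bad.index[bad][0]) if bad.any() else 0
        kind = "time" if col == time_col else "OD"
        raise ParseError(f"non-numeric {kind} value at row {row + 2}, column {col!r}")
    times = raw[time_col]
    if times.isna().any():
        row = int(times.index[times.isna()][0])
        raise ParseError(f"non-numeric time value at row {row + 2}, column {time_col!r}")
    for col in raw.columns[1:]:
        data[col] = raw[col].to_numpy(dtype=float)
    hours = times.to_numpy(dtype=float) / _TIME_DIVISOR[time_unit]
    order = np.argsort(hours, kind="stable")
    frame = pd.DataFrame(data).iloc[order].reset_index(drop=True)
    return PlateTable(
        times=hours[order],
        readings=frame,
        metadata={"source": str(path), "time_unit": "hours"},
    )


def write_plate_table(plate: PlateTable, path) -> None:
    """Write a plate table in the canonical CSV dialect (times in hours)."""
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    out = plate.readings.copy()
    out.insert(0, "time", plate.times)
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Plate layouts
# ---------------------------------------------------------------------------


@dataclass
class WellAssignment:
    strain: str
    carbon_source: str
    replicate: int
    role: str  # "sample" | "blank"


@dataclass
class PlateLayout:
    """Mapping of wells to strain / carbon source / replicate / role."""

    wells: dict[str, WellAssignment]

    def __post_init__(self) -> None:
        for well, info in self.wells.items():
            if not WELL_ID_RE.match(well):
                raise ParseError(f"well id {well!r} outside 96-well plate geometry")
            if info.role not in ("sample", "blank"):
                raise ParseError(f"unknown role {info.role!r} for well {well}")
        if not self.sample_wells:
            raise ParseError("layout has no sample wells")

    @property
    def sample_wells(self) -> list[str]:
        return [w for w, i in self.wells.items() if i.role == "sample"]

    @property
    def blank_wells(self) -> list[str]:
        return [w for w, i in self.wells.items() if i.role == "blank"]

    @property
    def blank_count(self) -> int:
        return len(self.blank_wells)


def read_layout(path) -> PlateLayout:
    """Read a plate layout (TSV or YAML).

    Emits a warning (not an error) when fewer than six blank wells are
    present: a larger blank panel is standard practice but not a validity
    requirement.
    """
    path = Path(path)
    wells: dict[str, WellAssignment] = {}
    if path.suffix in (".yaml", ".yml"):
        doc = yaml.safe_load(path.read_text())
        items = (doc.get("wells") if isinstance(doc, dict) and "wells" in doc else doc) or {}
        for well, info in items.items():
            if well in wells:
                raise ParseError(f"duplicate well {well} in layout")
            wells[str(well)] = WellAssignment(
                strain=str(info.get("strain", "")),
                carbon_source=str(info.get("carbon_source", "")),
                replicate=int(info.get("replicate", 1)),
                role=str(info.get("role", "sample")),
            )
    else:
        table = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
        required = {"well", "role"}
        if not required.issubset(table.columns):
            raise ParseError(f"layout must have columns {sorted(required)}")
        for idx, row in table.iterrows():
            well = str(row["well"]).strip()
            if well in wells:
                raise ParseError(f"duplicate well {well} in layout (row {idx + 2})")
            wells[well] = WellAssignment(
                strain=str(row.get("strain", "") or ""),
                carbon_source=str(row.get("carbon_source", "") or ""),
                replicate=int(row.get("replicate", 1) or 1),
                role=str(row["role"]).strip(),
            )
    layout = PlateLayout(wells=wells)
    if layout.blank_count < 6:
        warnings.warn(
            f"layout has only {layout.blank_count} blank wells; "
            "at least six medium-only blanks are recommended",
            stacklevel=2,
        )
    return layout


def write_layout(layout: PlateLayout, path) -> None:
    rows = [
        {
            "well": w,
            "strain": a.strain,
            "carbon_source": a.carbon_source,
            "replicate": a.replicate,
            "role": a.role,
        }
        for w, a in layout.wells.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Chemostat records
# ---------------------------------------------------------------------------


@dataclass
class ChemostatRecord:
    """One steady-state chemostat observation, all concentrations in g/L.

    ``D`` is the dilution rate (1/h), ``S_in``/``S_res`` the feed and residual
    substrate, ``X`` the biomass dry weight, ``products`` maps compound name
    to concentration, and ``biomass_TOC`` (optional) is the biomass carbon in
    g-carbon/L as measured by total-organic-carbon analysis.
    """

    substrate: str
    D: float
    S_in: float
    S_res: float
    X: float
    products: dict[str, float] = field(default_factory=dict)
    biomass_TOC: float | None = None

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("dilution rate D must be > 0")
        if not (self.S_in >= self.S_res >= 0):
            raise ValueError("feed substrate must satisfy S_in >= S_res >= 0")
        if self.X <= 0:
            raise ValueError("biomass concentration X must be > 0")
        for name, conc in self.products.items():
            if conc < 0:
                raise ValueError(f"negative concentration for product {name!r}")


def read_chemostat_table(path) -> list[ChemostatRecord]:
    table = pd.read_csv(path, sep=_detect_sep(Path(path)))
    records = []
    for _, row in table.iterrows():
        products = {
            name: float(row[name])
            for name in PRODUCT_COLUMNS
            if name in table.columns and pd.notna(row[name])
        }
        if "co2" in table.columns and pd.notna(row.get("co2")):
            products["co2"] = float(row["co2"])
        toc = row.get("biomass_TOC")
        records.append(
            ChemostatRecord(
                substrate=str(row["substrate"]),
                D=float(row["D"]),
                S_in=float(row["S_in"]),
                S_res=float(row["S_res"]),
                X=float(row["X"]),
                products=products,
                biomass_TOC=float(toc) if pd.notna(toc) else None,
            )
        )
    return records


def write_chemostat_table(records: Sequence[ChemostatRecord], path) -> None:
    rows = []
    for rec in records:
        row = {
            "substrate": rec.substrate,
            "D": rec.D,
            "S_in": rec.S_in,
            "S_res": rec.S_res,
            "X": rec.X,
        }
        for name in PRODUCT_COLUMNS:
            row[name] = rec.products.get(name, 0.0)
        if "co2" in rec.products:
            row["co2"] = rec.products["co2"]
        row["biomass_TOC"] = rec.biomass_TOC if rec.biomass_TOC is not None else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Variants and gene models
# ---------------------------------------------------------------------------

_ALLELE_RE = re.compile(r"^([ACGT]+|-)$")


@dataclass
class VariantRecord:
    """A single variant call: 1-based position, ref/alt alleles, support.

    ``-`` marks the absent side of an indel; a named token (e.g. an insertion
    element such as ``ISCth1``) is allowed as the alt allele.  ``frequency``
    is the fraction of supporting reads; ``depth`` the total reads at the
    position.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    frequency: float
    depth: int
    isolate: str = ""
    type: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")
        if self.ref == "-" and self.alt == "-":
            raise ValueError("ref and alt cannot both be '-'")
        if not _ALLELE_RE.match(self.ref):
            raise ValueError(f"invalid ref allele {self.ref!r}")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError("frequency must lie in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def is_named_insertion(self) -> bool:
        """True when the alt allele is a named mobile-element token."""
        return not _ALLELE_RE.match(self.alt)


def read_variant_table(path) -> list[VariantRecord]:
    table = pd.read_csv(path, sep=_detect_sep(Path(path)), dtype=str)
    records = []
    for _, row in table.iterrows():
        records.append(
            VariantRecord(
                contig=str(row["contig"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                frequency=float(row["frequency"]),
                depth=int(float(row["depth"])),
                isolate=str(row.get("isolate", "") or ""),
                type=str(row.get("type", "") or ""),
            )
        )
    return records


def write_variant_table(records: Sequence[VariantRecord], path) -> None:
    rows = [
        {
            "contig": r.contig,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "type": r.type,
            "isolate": r.isolate,
            "frequency": repr(r.frequency),
            "depth": r.depth,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf(path, isolate: str | None = None) -> list[VariantRecord]:
    """Minimal VCF reader: CHROM, POS, REF, ALT plus AF/DP from INFO.

    Multi-allelic records must be split upstream; the full VCF specification
    is out of scope.  Symbolic/indel alleles are converted to the internal
    anchored convention (``-`` on the absent side).
    """
    path = Path(path)
    if isolate is None:
        isolate = path.stem
    records = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ParseError(f"malformed VCF line: {line[:60]!r}")
        chrom, pos, _id, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
        info = dict(
            kv.split("=", 1) if "=" in kv else (kv, "")
            for kv in fields[7].split(";")
            if kv
        )
        freq = float(info.get("AF", 1.0))
        depth = int(info.get("DP", 0))
        if len(ref) > 1 and len(alt) == 1 and ref.startswith(alt):
            # anchored deletion, e.g. REF=AT ALT=A
            pos, ref, alt = pos + 1, ref[1:], "-"
        elif len(alt) > 1 and len(ref) == 1 and alt.startswith(ref):
            # anchored insertion, e.g. REF=A ALT=AT
            ref, alt = "-", alt[1:]
        records.append(
            VariantRecord(
                contig=chrom, pos=pos, ref=ref, alt=alt,
                frequency=freq, depth=depth, isolate=isolate,
            )
        )
    return records


@dataclass
class GeneModel:
    """A CDS gene model with 1-based inclusive genomic coordinates."""

    gene: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start must be <= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene}: strand must be '+' or '-'")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(f"gene {self.gene}: CDS length not divisible by 3")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from TSV or a GFF3 subset (CDS features only)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3_cds(path)
    table = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    return [
        GeneModel(
            gene=str(row["gene"]),
            contig=str(row["contig"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=str(row["strand"]),
            product=str(row.get("product", "") or ""),
        )
        for _, row in table.iterrows()
    ]


def _read_gff3_cds(path: Path) -> list[GeneModel]:
    genes = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"malformed GFF3 line: {line[:60]!r}")
        if fields[2] != "CDS":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        genes.append(
            GeneModel(
                gene=attrs.get("ID", attrs.get("Name", f"cds_{len(genes) + 1}")),
                contig=fields[0],
                start=int(fields[3]),
                end=int(fields[4]),
                strand=fields[6],
                product=attrs.get("product", ""),
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    rows = [
        {
            "gene": g.gene,
            "contig": g.contig,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "product": g.product,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Result reports
# ---------------------------------------------------------------------------


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)
    return str(value)


def _disp(value, decimals: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.{decimals}f}"


def _growth_row(fit, layout: PlateLayout | None) -> dict:
    strain = carbon = ""
    if layout is not None and fit.well in layout.wells:
        strain = layout.wells[fit.well].strain
        carbon = layout.wells[fit.well].carbon_source
    na = fit.status == "no_growth"
    mu = None if na else fit.mu
    lag = None if na else fit.lag
    return {
        "well": fit.well,
        "strain": strain,
        "carbon_source": carbon,
        "status": fit.status,
        "mu": _fmt(mu),
        "mu_display": _disp(mu, 2),
        "lag": _fmt(lag),
        "lag_display": _disp(lag, 1),
        "t_start": _fmt(None if na else fit.t_start),
        "t_end": _fmt(None if na else fit.t_end),
        "r2": _fmt(None if na else fit.r2),
        "n_points": fit.n_points,
        "seed_slope": _fmt(None if na else fit.seed_slope),
        "diauxic": fit.diauxic,
        "lag_adjusted": _fmt(fit.lag_adjusted),
        "flags": ";".join(fit.flags),
    }


def _physiology_row(res) -> dict:
    row = {
        "substrate": res.substrate,
        "D": _fmt(res.D),
        "q_substrate": _fmt(res.q_substrate),
        "q_display": _disp(res.q_substrate, 2),
        "Y_biomass": _fmt(res.Y_biomass),
        "Y_biomass_display": _disp(res.Y_biomass, 2),
    }
    for name in PRODUCT_COLUMNS:
        row[f"Y_{name}"] = _fmt(res.Y_products.get(name, 0.0))
    row["Y_co2_est"] = _fmt(res.Y_co2_est)
    row["Y_co2_display"] = _disp(res.Y_co2_est, 2)
    row["carbon_recovery"] = _fmt(res.carbon_recovery)
    row["carbon_recovery_display"] = _disp(res.carbon_recovery, 1)
    row["flags"] = ";".join(res.flags)
    return row


def _consequence_row(item) -> dict:
    record, cons = item
    return {
        "contig": record.contig,
        "pos": record.pos,
        "ref": record.ref,
        "alt": record.alt,
        "isolate": record.isolate,
        "frequency": _fmt(record.frequency),
        "depth": record.depth,
        "category": cons.category,
        "gene": cons.gene or "",
        "notation": cons.notation or "",
        "distance_bp": "" if cons.distance_bp is None else cons.distance_bp,
        "orientation": cons.orientation or "",
    }


def _summary_row(summary) -> dict:
    return {
        "strain": summary.strain,
        "carbon_source": summary.carbon_source,
        "mu_mean": _fmt(summary.mu_mean),
        "mu_mean_display": _disp(summary.mu_mean, 2),
        "mu_sd": _fmt(summary.mu_sd),
        "lag_mean": _fmt(summary.lag_mean),
        "lag_mean_display": _disp(summary.lag_mean, 1),
        "lag_sd": _fmt(summary.lag_sd),
        "n_total": summary.n_total,
        "n_growth": summary.n_growth,
        "growth_fraction": _fmt(summary.growth_fraction),
    }


_HEADERS = {
    "growth": [
        "well", "strain", "carbon_source", "status", "mu", "mu_display",
        "lag", "lag_display", "t_start", "t_end", "r2", "n_points",
        "seed_slope", "diauxic", "lag_adjusted", "flags",
    ],
    "physiology": [
        "substrate", "D", "q_substrate", "q_display", "Y_biomass",
        "Y_biomass_display",
        *[f"Y_{name}" for name in PRODUCT_COLUMNS],
        "Y_co2_est", "Y_co2_display", "carbon_recovery",
        "carbon_recovery_display", "flags",
    ],
    "variants": [
        "contig", "pos", "ref", "alt", "isolate", "frequency", "depth",
        "category", "gene", "notation", "distance_bp", "orientation",
    ],
    "summary": [
        "strain", "carbon_source", "mu_mean", "mu_mean_display", "mu_sd",
        "lag_mean", "lag_mean_display", "lag_sd", "n_total", "n_growth",
        "growth_fraction",
    ],
}


def _infer_kind(item) -> str:
    name = type(item).__name__
    if name == "GrowthFit":
        return "growth"
    if name == "PhysiologyResult":
        return "physiology"
    if name == "ReplicateSummary":
        return "summary"
    if isinstance(item, tuple) and len(item) == 2:
        return "variants"
    raise TypeError(f"cannot infer result kind for {name}")


def write_results(results: Iterable, path, kind: str | None = None,
                  layout: PlateLayout | None = None) -> None:
    """Write a result collection as a TSV report.

    Column orders are fixed per result kind (see ``_HEADERS``); floats are
    written at full precision with an additional rounded display column, and
    NA fields appear as empty strings.  ``kind`` is only needed for empty
    collections where it cannot be inferred.
    """
    results = list(results)
    if kind is None:
        if not results:
            raise ValueError("kind must be given for an empty result collection")
        kind = _infer_kind(results[0])
    if kind not in _HEADERS:
        raise ValueError(f"unknown result kind {kind!r}")
    builders = {
        "growth": lambda item: _growth_row(item, layout),
        "physiology": _physiology_row,
        "variants": _consequence_row,
        "summary": _summary_row,
    }
    rows = [builders[kind](item) for item in results]
    frame = pd.DataFrame(rows, columns=_HEADERS[kind])
    frame.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    """Read back a result report written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
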