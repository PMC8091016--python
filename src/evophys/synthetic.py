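"""Synthetic data generators with known ground truth.

Every pipeline stage has a matching generator so the whole analysis is
testable without external downloads:

* **Plate-reader traces** follow a delayed-logistic model: OD is flat at the
  inoculation density until the lag time, then grows logistically toward a
  carrying capacity.  Sampling every 5 min over an 80-h horizon, a starting
  OD of 0.02, and additive Gaussian noise (SD 0.006, truncated at zero)
  emulate the batch screening conditions this pipeline targets.  Diauxic
  traces are piecewise: a first exponential phase, a plateau, then a second
  delayed-logistic phase.
* **Plates** combine sample wells with at least six medium-only blank wells
  whose across-well scatter stays below the 0.006 noise regime.
* **Chemostat records** allocate consumed-substrate carbon to biomass and
  products; carbon-closed records assign the residual carbon to CO2 so the
  carbon recovery is exactly 100%.
* **Toy genomes** carry non-overlapping CDSs (ATG ... stop) on both strands
  with spiked variants of known category; frequencies and depths straddle
  the 35% / 10-read filter boundary.

All generators are deterministic for a fixed seed, and ground truth is
recorded alongside every dataset (never altered post hoc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    PlateLayout,
    PlateTable,
    VariantRecord,
    WellAssignment,
    ChemostatRecord,
)
from .chemostat import COMPOUNDS, CARBON_MASS
from .growth_fit import ODTrace

__all__ = [
    "TraceParams",
    "simulate_trace",
    "simulate_plate",
    "simulate_chemostat_record",
    "simulate_toy_genome_with_variants",
]

_ROWS = "ABCDEFGH"
_WELL_IDS = [f"{r}{c}" for r in _ROWS for c in range(1, 13)]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class TraceParams:
    """Ground-truth parameters of one simulated OD trace.

    ``mu`` (1/h) and ``lag`` (h) are the quantities the estimator should
    recover; ``od0`` is the inoculation density, ``K`` the carrying
    capacity, ``noise_sd`` the additive OD noise.  A diauxic trace is
    requested by setting ``mu2``: the first phase then runs at ``mu`` for
    ``phase1_h`` hours, pauses for ``plateau_h``, and the main phase grows
    at ``mu2`` toward ``K``.
    """

    mu: float = 0.3
    lag: float = 0.0
    od0: float = 0.02
    K: float = 1.0
    noise_sd: float = 0.006
    horizon_h: float = 80.0
    dt_min: float = 5.0
    baseline: float = 0.0
    mu2: float | None = None
    phase1_h: float = 4.0
    plateau_h: float = 6.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not (0 < self.od0 < self.K):
            raise ValueError("need 0 < od0 < K")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.horizon_h <= self.lag:
            raise ValueError("horizon must exceed the lag time")


def _delayed_logistic(t: np.ndarray, mu: float, lag: float, od0: float, K: float) -> np.ndarray:
    od = np.full_like(t, od0, dtype=float)
    after = t >= lag
    e = np.exp(mu * (t[after] - lag))
    od[after] = K * od0 * e / (K - od0 + od0 * e)
    return od


def simulate_trace(p: TraceParams, seed=None, well: str = "SIM") -> ODTrace:
    """Simulate one (uncorrected) OD trace; deterministic for a fixed seed.

    The returned trace includes the baseline offset and noise; its mask is
    derived from the default noise floor on the noiseless signal's scale,
    so callers typically re-derive masks after blank correction.
    """
    rng = np.random.default_rng(seed)
    n = int(round(p.horizon_h * 60.0 / p.dt_min)) + 1
    t = np.arange(n) * (p.dt_min / 60.0)
    if p.mu2 is None:
        od = _delayed_logistic(t, p.mu, p.lag, p.od0, p.K)
    else:
        od = np.full_like(t, p.od0)
        e1 = p.lag + p.phase1_h
        t2 = e1 + p.plateau_h
        od1 = p.od0 * math.exp(p.mu * p.phase1_h)
        phase1 = (t >= p.lag) & (t < e1)
        od[phase1] = p.od0 * np.exp(p.mu * (t[phase1] - p.lag))
        od[(t >= e1) & (t < t2)] = od1
        main = t >= t2
        od[main] = _delayed_logistic(t[main], p.mu2, t2, od1, p.K)
    od = od + p.baseline
    if p.noise_sd > 0:
        od = np.maximum(od + rng.normal(0.0, p.noise_sd, size=n), 0.0)
    return ODTrace(well=well, times=t, od=od)


def simulate_plate(
    groups: Sequence[tuple[str, str, TraceParams, int]],
    n_blanks: int = 6,
    baseline: float = 0.08,
    blank_noise_sd: float = 0.002,
    seed=None,
) -> tuple[PlateTable, PlateLayout, pd.DataFrame]:
    """Simulate a 96-well plate: sample wells per group plus blank wells.

    ``groups`` holds (strain, carbon_source, TraceParams, n_replicates).
    Blanks are baseline plus noise whose across-well SD stays below the
    0.006 regime by default.  Returns the plate, its layout, and a truth
    table with the generating parameters per well.
    """
    rng = np.random.default_rng(seed)
    n_samples = sum(n for _, _, _, n in groups)
    if n_samples + n_blanks > 96:
        raise ValueError(f"{n_samples} samples + {n_blanks} blanks exceed 96 wells")
    if n_samples + n_blanks == 0:
        raise ValueError("empty plate")

    wells: dict[str, WellAssignment] = {}
    columns: dict[str, np.ndarray] = {}
    truth_rows = []
    times = None
    idx = 0
    for strain, carbon, params, n_reps in groups:
        for rep in range(1, n_reps + 1):
            well = _WELL_IDS[idx]
            idx += 1
            trace = simulate_trace(
                TraceParams(**{**params.__dict__, "baseline": baseline}),
                seed=rng.integers(0, 2**31 - 1),
                well=well,
            )
            times = trace.times
            columns[well] = trace.od
            wells[well] = WellAssignment(strain=strain, carbon_source=carbon,
                                         replicate=rep, role="sample")
            truth_rows.append(
                {
                    "well": well, "strain": strain, "carbon_source": carbon,
                    "replicate": rep, "mu_true": params.mu,
                    "lag_true": params.lag, "od0": params.od0, "K": params.K,
                    "noise_sd": params.noise_sd,
                    "mu2_true": params.mu2 if params.mu2 is not None else np.nan,
                }
            )
    if times is None:  # blank-only plate: use the default sampling grid
        ref = TraceParams()
        n = int(round(ref.horizon_h * 60.0 / ref.dt_min)) + 1
        times = np.arange(n) * (ref.dt_min / 60.0)
    for b in range(n_blanks):
        well = _WELL_IDS[idx]
        idx += 1
        columns[well] = np.maximum(
            baseline + rng.normal(0.0, blank_noise_sd, size=len(times)), 0.0
        )
        wells[well] = WellAssignment(strain="blank", carbon_source="",
                                     replicate=b + 1, role="blank")
    # a blank-only plate has no sample wells, which PlateLayout rejects;
    # register a dummy-free layout only when samples exist
    if n_samples == 0:
        layout = PlateLayout.__new__(PlateLayout)
        layout.wells = wells
    else:
        layout = PlateLayout(wells=wells)
    plate = PlateTable(times=times, readings=pd.DataFrame(columns),
                       metadata={"simulated": True})
    return plate, layout, pd.DataFrame(truth_rows)


def simulate_chemostat_record(
    substrate: str = "glucose",
    D: float = 0.10,
    S_in: float = 4.8,
    S_res: float = 0.02,
    Y_biomass_true: float = 0.09,
    product_carbon_split: dict[str, float] | None = None,
    biomass_carbon_fraction: float = 0.47,
    carbon_closed: bool = True,
    noise_rel: float = 0.0,
    seed=None,
) -> tuple[ChemostatRecord, dict]:
    """Simulate one steady-state record with known yields.

    ``product_carbon_split`` maps product names to the fraction of consumed
    substrate carbon they receive.  With ``carbon_closed`` the remaining
    carbon (after biomass) goes to CO2 and the biomass TOC is set to the
    biomass carbon, so the carbon recovery is exactly 100%.  Multiplicative
    Gaussian noise of relative SD ``noise_rel`` perturbs the measured
    concentrations (truth is kept separately).
    """
    rng = np.random.default_rng(seed)
    if product_carbon_split is None:
        product_carbon_split = {"ethanol": 0.25, "acetate": 0.25, "formate": 0.03}
    sub = COMPOUNDS[substrate]
    consumed = S_in - S_res
    if consumed <= 0:
        raise ValueError("need S_in > S_res")
    consumed_c = consumed * sub.n_carbon / sub.molar_mass  # mol C / L
    X = Y_biomass_true * consumed
    biomass_c = X * biomass_carbon_fraction / CARBON_MASS  # mol C / L
    biomass_frac = biomass_c / consumed_c
    split_sum = sum(product_carbon_split.values())
    if split_sum + biomass_frac > 1.0 + 1e-9:
        raise ValueError(
            f"infeasible carbon split: products ({split_sum:.3f}) + biomass "
            f"({biomass_frac:.3f}) exceed the consumed carbon"
        )
    products = {}
    for name, frac in product_carbon_split.items():
        spec = COMPOUNDS[name]
        products[name] = frac * consumed_c * spec.molar_mass / spec.n_carbon
    biomass_TOC = biomass_c * CARBON_MASS
    if carbon_closed:
        co2_c = consumed_c - sum(
            conc * COMPOUNDS[name].n_carbon / COMPOUNDS[name].molar_mass
            for name, conc in products.items()
        ) - biomass_c
        products["co2"] = co2_c * COMPOUNDS["co2"].molar_mass
    truth = {
        "substrate": substrate, "D": D, "S_in": S_in, "S_res": S_res,
        "X_true": X, "Y_biomass_true": Y_biomass_true,
        "products_true": dict(products), "biomass_TOC_true": biomass_TOC,
        "carbon_closed": carbon_closed,
    }
    if noise_rel > 0:
        X = X * (1.0 + rng.normal(0.0, noise_rel))
        products = {
            name: conc * (1.0 + rng.normal(0.0, noise_rel))
            for name, conc in products.items()
        }
        biomass_TOC = biomass_TOC * (1.0 + rng.normal(0.0, noise_rel))
    record = ChemostatRecord(
        substrate=substrate, D=D, S_in=S_in, S_res=S_res, X=X,
        products=products, biomass_TOC=biomass_TOC,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Toy genomes with spiked variants
# ---------------------------------------------------------------------------


def _codon_change_tables():
    """Single-base codon changes grouped by effect (synonymous/missense/stop)."""
    from Bio.Data import CodonTable

    t11 = CodonTable.unambiguous_dna_by_id[11]

    def aa(codon):
        return "*" if codon in t11.stop_codons else t11.forward_table[codon]

    syn, mis, non = {}, {}, {}
    for c1 in "ACGT":
        for c2 in "ACGT":
            for c3 in "ACGT":
                codon = c1 + c2 + c3
                if codon in t11.stop_codons:
                    continue
                ref_aa = aa(codon)
                for off in range(3):
                    for b in "ACGT":
                        if b == codon[off]:
                            continue
                        alt = codon[:off] + b + codon[off + 1 :]
                        alt_aa = aa(alt)
                        if alt_aa == ref_aa:
                            syn.setdefault(codon, []).append((off, b))
                        elif alt_aa == "*":
                            non.setdefault(codon, []).append((off, b))
                        else:
                            mis.setdefault(codon, []).append((off, b))
    return syn, mis, non


_SYN_CHANGES, _MIS_CHANGES, _NON_CHANGES = _codon_change_tables()

_DEFAULT_TYPE_MIX = {
    "synonymous": 0.2,
    "missense": 0.3,
    "nonsense": 0.1,
    "frameshift": 0.2,
    "intergenic": 0.2,
}


def _random_cds(rng, n_codons: int) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def simulate_toy_genome_with_variants(
    n_genes: int = 6,
    gene_length_codons: int = 60,
    frac_reverse: float = 0.5,
    n_variants: int = 100,
    type_mix: dict[str, float] | None = None,
    spacer_bp: int = 150,
    n_isolates: int = 4,
    contig: str = "toy_contig_1",
    seed=None,
):
    """Build a toy genome, gene models, and spiked variants with known truth.

    Genes are random CDSs (ATG ... stop) separated by random spacers, placed
    on either strand; variants are spiked with a known category by codon
    construction.  Frequencies ~ U(0.1, 1) and depths ~ U{5..100} exercise
    the 35% / 10-read filter boundary.  Returns
    ``(genome, genes, variants, truth)`` where ``truth`` is a DataFrame with
    the constructed category (and residue for coding changes) per variant.
    """
    rng = np.random.default_rng(seed)
    type_mix = type_mix or _DEFAULT_TYPE_MIX
    categories = list(type_mix)
    probs = np.array([type_mix[c] for c in categories], dtype=float)
    probs = probs / probs.sum()

    # --- genome assembly -------------------------------------------------
    parts = []
    genes: list[GeneModel] = []
    cursor = 0
    for g in range(n_genes):
        spacer = "".join(rng.choice(list("ACGT"), size=spacer_bp))
        parts.append(spacer)
        cursor += spacer_bp
        cds = _random_cds(rng, gene_length_codons)
        strand = "-" if rng.random() < frac_reverse else "+"
        placed = cds if strand == "+" else cds.translate(_COMPLEMENT)[::-1]
        parts.append(placed)
        genes.append(
            GeneModel(
                gene=f"gene_{g + 1:04d}", contig=contig,
                start=cursor + 1, end=cursor + len(placed), strand=strand,
                product="synthetic CDS",
            )
        )
        cursor += len(placed)
    parts.append("".join(rng.choice(list("ACGT"), size=spacer_bp)))
    genome_seq = "".join(parts)
    genome = {contig: genome_seq}

    # --- variant spiking -------------------------------------------------
    def genomic_pos(gene: GeneModel, cds_pos: int) -> int:
        return gene.start + cds_pos - 1 if gene.strand == "+" else gene.end - cds_pos + 1

    def gene_cds(gene: GeneModel) -> str:
        region = genome_seq[gene.start - 1 : gene.end]
        return region.translate(_COMPLEMENT)[::-1] if gene.strand == "-" else region

    variants: list[VariantRecord] = []
    truth_rows = []
    n_codons = gene_length_codons
    for i in range(n_variants):
        category = categories[rng.choice(len(categories), p=probs)]
        isolate = f"iso_{(i % n_isolates) + 1}"
        frequency = float(rng.uniform(0.1, 1.0))
        depth = int(rng.integers(5, 101))
        residue = None
        if category == "intergenic":
            # a position inside a spacer, at least 2 bp from any gene
            while True:
                pos = int(rng.integers(3, len(genome_seq) - 2)) + 1
                if all(not (g.start - 1 <= pos <= g.end + 1) for g in genes):
                    break
            ref = genome_seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            vtype = "SNV"
        elif category == "frameshift":
            gene = genes[rng.integers(0, n_genes)]
            # avoid the start and stop codons; leave headroom for alignment
            codon = int(rng.integers(1, n_codons - 2))
            residue = codon + 1
            cds_pos = 3 * codon + 1 + int(rng.integers(0, 3))
            if rng.random() < 0.5:  # 1-bp deletion at cds_pos
                pos = genomic_pos(gene, cds_pos)
                if gene.strand == "-":
                    pos = genomic_pos(gene, cds_pos)  # single base: same site
                ref, alt, vtype = genome_seq[pos - 1], "-", "Del"
            else:  # 1-bp insertion first affecting cds_pos
                if gene.strand == "+":
                    pos = genomic_pos(gene, cds_pos) - 1
                else:
                    pos = genomic_pos(gene, cds_pos)
                ref, alt, vtype = "-", str(rng.choice(list("ACGT"))), "In"
        else:
            tables = {
                "synonymous": _SYN_CHANGES,
                "missense": _MIS_CHANGES,
                "nonsense": _NON_CHANGES,
            }[category]
            while True:
                gene = genes[rng.integers(0, n_genes)]
                codon_idx = int(rng.integers(1, n_codons - 1))
                cds = gene_cds(gene)
                codon = cds[3 * codon_idx : 3 * codon_idx + 3]
                if codon in tables:
                    break
            off, new_base = tables[codon][rng.integers(0, len(tables[codon]))]
            residue = codon_idx + 1
            cds_pos = 3 * codon_idx + 1 + off
            pos = genomic_pos(gene, cds_pos)
            if gene.strand == "+":
                ref, alt = codon[off], new_base
            else:
                ref = codon[off].translate(_COMPLEMENT)
                alt = new_base.translate(_COMPLEMENT)
            vtype = "SNV"
        variants.append(
            VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt,
                          frequency=frequency, depth=depth, isolate=isolate,
                          type=vtype)
        )
        truth_rows.append(
            {
                "pos": pos, "ref": ref, "alt": alt, "category": category,
                "residue": residue if residue is not None else np.nan,
                "isolate": isolate, "frequency": frequency, "depth": depth,
                "passes_default_filter": frequency >= 0.35 and depth >= 10,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return genome, genes, variants, truth
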