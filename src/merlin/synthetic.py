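"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates (i) cell-tagged 3'-biased reads carrying anchored semi-random
barcodes, (ii) exponential growth/decay clone abundance trajectories over the
study timepoints, (iii) burden-matched random mutation profiles with an
optional planted recurrent gene, (iv) noisy copy-number matrices centered at
1 with planted aberrant segments, and (v) structured spatial fields and mask
pairs.  Every generator is deterministic under a fixed seed and returns a
complete ground-truth record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from merlin.barcode_design import (
    BarcodeBlueprint,
    default_blueprint,
    sample_barcode,
    sample_suffix,
)
from merlin.dynamics import TimepointMeta
from merlin.extract import (
    CLONE_ID_LENGTH,
    DEFAULT_EMPTY_VECTOR_SIGNATURE,
    TaggedRead,
    reverse_complement,
)
from merlin.recurrence import MutationProfiles

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for the clone-trajectory simulation.

    Defaults mirror the in vivo design: four sampling days (pre-treatment,
    early and late minimal residual disease, resistant endpoint), treatment
    starting at ~500 mm³ tumors, persister expansion and sensitive decline on
    per-day exponential rates, and multiplicative log-normal measurement
    noise.
    """

    n_clones: int = 300
    fate_fractions: tuple[float, float, float] = (0.3, 0.5, 0.2)  # persister, sensitive, low
    growth_rate: float = 0.08  # per day
    decay_rate: float = 0.10  # per day
    timepoints: tuple[int, ...] = (0, 21, 57, 91)
    noise_sd: float = 0.1  # log-normal sigma on abundances
    dirichlet_conc: float = 5.0  # initial clone-size concentration
    baseline_volume: float = 500.0  # mm^3 at day 0
    low_abundance_max: float = 1e-4  # proportion ceiling for planted low clones
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fate_fractions) - 1.0) > 1e-9:
            raise ValueError("fate fractions must sum to 1")
        if self.growth_rate <= 0 or self.decay_rate <= 0:
            raise ValueError("rates must be > 0")
        if len(self.timepoints) < 2:
            raise ValueError("at least 2 timepoints required")


@dataclass
class GroundTruth:
    """Complete truth records for one simulation."""

    clone_fates: dict[str, str] = field(default_factory=dict)
    clone_params: dict[str, dict] = field(default_factory=dict)
    cell_clones: dict[str, str] = field(default_factory=dict)
    decoy_reads: dict[str, str] = field(default_factory=dict)  # read_id -> decoy kind
    planted_genes: dict[str, int] = field(default_factory=dict)
    planted_segments: list[dict] = field(default_factory=list)
    spatial_structure: str | None = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# clone trajectories

def simulate_trajectories(
    sc: SimScenario, bp: BarcodeBlueprint | None = None
) -> tuple[pd.DataFrame, list[TimepointMeta], GroundTruth]:
    """Clone proportion table, timepoint metadata and truth for a scenario.

    Persister clones follow ``a0·exp(k·t)``, sensitive clones ``a0·exp(−k·t)``
    and low-abundance clones a small constant, each perturbed by multiplicative
    log-normal noise; columns are renormalized to proportions.  Tumor volume
    tracks total simulated cell mass from the baseline volume, so normalized
    abundance (proportion × volume) recovers each clone's exponential form.
    """
    bp = bp or default_blueprint()
    rng = np.random.default_rng(sc.seed)
    t = np.asarray(sc.timepoints, dtype=float)

    n_pers = int(round(sc.n_clones * sc.fate_fractions[0]))
    n_sens = int(round(sc.n_clones * sc.fate_fractions[1]))
    n_low = sc.n_clones - n_pers - n_sens
    labels = ["persister"] * n_pers + ["sensitive"] * n_sens + ["low_abundance"] * n_low

    clone_ids: list[str] = []
    seen: set[str] = set()
    while len(clone_ids) < sc.n_clones:
        cid = sample_suffix(bp, rng, CLONE_ID_LENGTH)
        if cid not in seen:
            seen.add(cid)
            clone_ids.append(cid)

    a0 = rng.dirichlet(np.full(sc.n_clones, sc.dirichlet_conc))
    # low clones sit well below the low-abundance proportion ceiling
    low_scale = rng.uniform(0.2, 0.5, size=sc.n_clones) * sc.low_abundance_max

    abundance = np.empty((sc.n_clones, t.size))
    truth = GroundTruth()
    for i, (cid, lab) in enumerate(zip(clone_ids, labels)):
        if lab == "persister":
            base, k = a0[i], sc.growth_rate
            abundance[i] = base * np.exp(k * t)
        elif lab == "sensitive":
            base, k = a0[i], sc.decay_rate
            abundance[i] = base * np.exp(-k * t)
        else:
            base, k = low_scale[i], 0.0
            abundance[i] = base
        truth.clone_fates[cid] = lab
        truth.clone_params[cid] = {"a0": float(base), "k": float(k)}
    if sc.noise_sd > 0:
        abundance *= rng.lognormal(0.0, sc.noise_sd, size=abundance.shape)

    totals = abundance.sum(axis=0)
    props = pd.DataFrame(abundance / totals, index=clone_ids,
                         columns=[f"day{int(d)}" for d in t])
    volumes = sc.baseline_volume * totals / totals[0]
    meta = [
        TimepointMeta(label=f"day{int(d)}", day=int(d), tumor_volume=float(v))
        for d, v in zip(t, volumes)
    ]
    return props, meta, truth


# ---------------------------------------------------------------------------
# tagged reads

def simulate_tagged_reads(
    assignments: dict[str, str],
    bp: BarcodeBlueprint | None = None,
    depth: int = 6,
    reads_per_umi: int = 1,
    error_rate: float = 0.0,
    no_anchor_rate: float = 0.0,
    empty_vector_rate: float = 0.0,
    multi_clone_cell_rate: float = 0.0,
    seed: int = 0,
    context_len: int = 30,
    tail_len: int = 10,
) -> tuple[list[TaggedRead], GroundTruth]:
    """Cell-tagged reads carrying each clone's barcode suffix and the anchor.

    ``assignments`` maps cell tags to 15-nt clone identifiers.  Each cell
    emits ``depth`` UMIs with ``reads_per_umi`` reads each.  Decoys: with
    ``no_anchor_rate`` the anchor is replaced by random bases; with
    ``empty_vector_rate`` the read carries the empty-vector signature instead
    of barcode; ``multi_clone_cell_rate`` of cells get half their reads from a
    second clone.  ``error_rate`` applies uniform substitutions to the barcode
    context of each read.  Half the reads are emitted reverse-complemented.
    """
    bp = bp or default_blueprint()
    rng = np.random.default_rng(seed)
    anchor = bp.right_flank_anchor
    truth = GroundTruth(cell_clones=dict(assignments))

    # a full barcode per clone, with the suffix forced to the clone id
    clone_barcodes: dict[str, str] = {}
    for clone in sorted(set(assignments.values())):
        full = sample_barcode(bp, rng)
        clone_barcodes[clone] = full[: len(full) - CLONE_ID_LENGTH] + clone

    clones_pool = sorted(clone_barcodes)
    reads: list[TaggedRead] = []
    for cell, clone in sorted(assignments.items()):
        second: str | None = None
        if len(clones_pool) > 1 and rng.random() < multi_clone_cell_rate:
            second = clones_pool[rng.integers(len(clones_pool))]
            while second == clone:
                second = clones_pool[rng.integers(len(clones_pool))]
            truth.decoy_reads[f"cell:{cell}"] = "multi_clone_cell"
        for u in range(depth):
            umi = "".join(_BASES[rng.integers(4, size=10)])
            src = clone
            if second is not None and u % 2 == 1:
                src = second
            for r in range(reads_per_umi):
                rid = f"{cell}:{u}:{r}"
                barcode = clone_barcodes[src]
                context = barcode[-context_len:]
                if rng.random() < empty_vector_rate:
                    context = DEFAULT_EMPTY_VECTOR_SIGNATURE
                    truth.decoy_reads[rid] = "empty_vector"
                elif error_rate > 0:
                    context = _mutate(context, error_rate, rng)
                anc = anchor
                if rng.random() < no_anchor_rate:
                    anc = "".join(_BASES[rng.integers(4, size=len(anchor))])
                    truth.decoy_reads[rid] = "no_anchor"
                tail = "".join(_BASES[rng.integers(4, size=tail_len)])
                seq = context + anc + tail
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
                reads.append(TaggedRead(rid, seq, cell, umi))
    return reads, truth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < rate:
            alt = "ACGT".replace(base, "") if base in "ACGT" else "ACGT"
            out[i] = alt[rng.integers(len(alt))]
    return "".join(out)


def write_fastq(reads: Sequence[TaggedRead], path: str) -> None:
    """FASTQ dialect with CB/UB as key=value header fields."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} CB={r.cell_tag} UB={r.umi}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_sam(reads: Sequence[TaggedRead], path: str) -> None:
    """Unaligned SAM with CB/UB tags."""
    header = pysam.AlignmentHeader.from_dict({"HD": {"VN": "1.6", "SO": "unsorted"}})
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for r in reads:
            rec = pysam.AlignedSegment(header)
            rec.query_name = r.read_id
            rec.query_sequence = r.seq
            rec.flag = 4  # unmapped
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            rec.set_tag("CB", r.cell_tag)
            rec.set_tag("UB", r.umi)
            fh.write(rec)


def assign_cells(
    clone_ids: Sequence[str],
    n_cells: int,
    seed: int = 0,
    weights: Sequence[float] | None = None,
) -> dict[str, str]:
    """Assign synthetic cell tags to clones (optionally abundance-weighted)."""
    rng = np.random.default_rng(seed)
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        p = w / w.sum()
    picks = rng.choice(len(clone_ids), size=n_cells, p=p)
    return {
        f"CELL{i:05d}-1": clone_ids[j] for i, j in enumerate(picks)
    }


# ---------------------------------------------------------------------------
# mutation profiles

def simulate_mutation_profiles(
    universe_size: int,
    burdens: Sequence[int],
    planted_recurrence: int = 0,
    planted_gene: str = "PLANTED1",
    seed: int = 0,
) -> tuple[MutationProfiles, GroundTruth]:
    """Burden-matched random mutation sets with a gene planted in r tumors.

    Per-tumor gene sets are uniform draws without replacement from the
    universe; the planted gene is then forced present in exactly
    ``planted_recurrence`` tumors and absent elsewhere, swapping single genes
    so burdens are preserved.
    """
    if planted_recurrence > len(burdens):
        raise ValueError("planted recurrence exceeds number of tumors")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(universe_size - 1)] + [planted_gene]
    universe = frozenset(genes)
    ordered = sorted(universe)
    tumors: dict[str, set[str]] = {}
    for i, b in enumerate(burdens):
        if b > len(ordered):
            raise ValueError("burden exceeds universe size")
        tumors[f"tumor{i + 1}"] = {ordered[j] for j in rng.choice(len(ordered), size=b, replace=False)}

    truth = GroundTruth()
    if planted_recurrence:
        chosen = list(rng.choice(sorted(tumors), size=planted_recurrence, replace=False))
        others = [g for g in ordered if g != planted_gene]
        for name, genes_t in tumors.items():
            if name in chosen and planted_gene not in genes_t:
                genes_t.remove(sorted(genes_t)[rng.integers(len(genes_t))])
                genes_t.add(planted_gene)
            elif name not in chosen and planted_gene in genes_t:
                genes_t.remove(planted_gene)
                replacement = others[rng.integers(len(others))]
                while replacement in genes_t:
                    replacement = others[rng.integers(len(others))]
                genes_t.add(replacement)
        truth.planted_genes[planted_gene] = planted_recurrence
    profiles = MutationProfiles({t: frozenset(g) for t, g in tumors.items()}, universe)
    return profiles, truth


def write_gmt(pathways: dict[str, Sequence[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# CNV matrices

def simulate_cnv_matrix(
    n_cells: int,
    n_genes: int,
    noise_sd: float = 0.0,
    planted_segments: Sequence[tuple[Sequence[int], int, int, float]] = (),
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cells × genes CNV matrix centered at 1 with planted aberrant blocks.

    Each planted segment is ``(cell_indices, gene_start, gene_len, shift)``:
    the contiguous gene block is shifted by ``shift`` for the listed cells.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    mat = np.full((n_cells, n_genes), 1.0)
    if noise_sd:
        mat += rng.normal(0.0, noise_sd, size=(n_cells, n_genes))
    truth = GroundTruth()
    for cells, start, length, shift in planted_segments:
        idx = np.asarray(list(cells), dtype=int)
        mat[np.ix_(idx, np.arange(start, start + length))] += shift
        truth.planted_segments.append(
            {"cells": idx.tolist(), "gene_start": int(start),
             "gene_len": int(length), "shift": float(shift)}
        )
    df = pd.DataFrame(
        mat,
        index=[f"cell{i:04d}" for i in range(n_cells)],
        columns=[f"gene{i:05d}" for i in range(n_genes)],
    )
    return df, truth


# ---------------------------------------------------------------------------
# spatial fields and masks

def simulate_spatial_field(
    nrows: int,
    ncols: int,
    structure: str = "random",
    seed: int = 0,
    block_frac: float = 0.5,
) -> tuple[np.ndarray, GroundTruth]:
    """Lattice field: 'checkerboard', 'clustered' (one block), or 'random'."""
    if nrows < 2 or ncols < 2:
        raise ValueError("grid must be at least 2x2")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(spatial_structure=structure)
    if structure == "checkerboard":
        rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
        grid = ((rr + cc) % 2).astype(float)
    elif structure == "clustered":
        grid = np.zeros((nrows, ncols))
        grid[: max(1, int(nrows * block_frac)), : max(1, int(ncols * block_frac))] = 1.0
    elif structure == "random":
        grid = rng.normal(size=(nrows, ncols))
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return grid, truth


def simulate_mask_pair(
    shape: tuple[int, int],
    mode: str = "independent",
    density: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two binary rasters: 'identical', 'independent', or 'disjoint' signal.

    Signal is laid down as small square blobs (so patch-level positivity is
    meaningful) at approximately the requested pixel density.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth(spatial_structure=f"masks:{mode}")

    def blobs(r: np.random.Generator) -> np.ndarray:
        m = np.zeros(shape, dtype=np.int8)
        blob = max(2, min(shape) // 20)
        n_blobs = max(1, int(density * shape[0] * shape[1] / blob**2))
        for _ in range(n_blobs):
            i = r.integers(shape[0] - blob + 1)
            j = r.integers(shape[1] - blob + 1)
            m[i : i + blob, j : j + blob] = 1
        return m

    a = blobs(rng)
    if mode == "identical":
        b = a.copy()
    elif mode == "independent":
        b = blobs(rng)
    elif mode == "disjoint":
        b = blobs(rng) & (1 - a)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return a, b, truth
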