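"""Synthetic plate-based scRNA-seq time course with known ground truth.

Emulates the data structure the analysis pipeline assumes: a latent
trajectory sampled at ordered conditions, discrete off-trajectory
populations, a dominant housekeeping gene, ERCC spike-in rows, deep
(Smart-Seq2-like) libraries, planted QC failures, index-sort fluorescence
tables and a DNA-content (Hoechst) mixture.

Counts are negative-binomial (gamma-Poisson) around gene/cell means that
follow each gene's planted program in log2 space, scaled to a lognormal
library size, then thinned by logistic dropout. Everything is deterministic
given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import RawCountMatrix, SPIKEIN_PREFIX

HOUSEKEEPING_GENE = "Actb"

PROGRAM_MONOTONE_UP = "monotone_up"
PROGRAM_MONOTONE_DOWN = "monotone_down"
PROGRAM_TRANSIENT = "transient"
PROGRAM_BACKGROUND = "background"
PROGRAM_SPIKEIN = "spikein"
PROGRAM_HOUSEKEEPING = "housekeeping"

TRAJECTORY_LABEL = "trajectory"

DEFAULT_CHANNELS = ("CD45", "CD11b", "BSC-A", "Hoechst")

WELLS_PER_PLATE = 384


@dataclass
class SimConfig:
    """Parameters of the synthetic time course.

    ``condition_times`` defaults to ``linspace(0, 1, n_conditions)``; the
    latent time of each cell is its condition's time plus bounded jitter.
    """

    n_conditions: int = 12
    condition_times: np.ndarray | None = None
    cells_per_condition: int = 150
    n_genes: int = 2000
    n_spikeins: int = 92
    n_monotone_up: int = 10
    n_monotone_down: int = 10
    n_transient: int = 10
    effect_size: float = 2.0
    libsize_log_mean: float = math.log(6e5)
    libsize_log_sd: float = 0.5
    dropout_midpoint: float = 2.0
    dropout_steepness: float = 1.0
    frac_low_count: float = 0.05
    frac_low_actb: float = 0.02
    off_trajectory_populations: int = 3
    cells_per_population: int = 100
    archetype_signature_size: int = 30
    archetype_effect: float = 3.0
    time_jitter: float = 0.02
    transient_width: float = 0.15
    dispersion_log_sd: float = 0.5
    dispersion_median: float = 0.3
    s_phase_fraction: float = 0.10
    n_bulk_controls: int = 2
    n_empty_controls: int = 2
    index_plate_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition_times is None:
            self.condition_times = np.linspace(0.0, 1.0, self.n_conditions)
        self.condition_times = np.asarray(self.condition_times, dtype=float)
        if len(self.condition_times) != self.n_conditions:
            raise ValueError("condition_times length must equal n_conditions")
        if np.any(np.diff(self.condition_times) <= 0):
            raise ValueError("condition_times must be strictly increasing")
        for name in ("frac_low_count", "frac_low_actb", "s_phase_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_conditions", "n_genes", "n_spikeins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        planted = self.n_monotone_up + self.n_monotone_down + self.n_transient
        # +1 for the housekeeping stand-in which occupies a gene slot
        if self.n_genes < planted + 1:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than planted programs ({planted}) + housekeeping"
            )


@dataclass
class TrajectoryTruth:
    """Machine-readable ground truth accompanying a simulated matrix."""

    cell_ids: np.ndarray
    latent_time: np.ndarray          # per cell, in [0, 1]
    population_label: np.ndarray     # "trajectory" or archetype name
    is_low_count: np.ndarray         # planted QC failures
    is_low_actb: np.ndarray
    s_phase: np.ndarray
    library_size: np.ndarray         # pre-dropout column sums
    gene_ids: np.ndarray
    program_membership: np.ndarray   # per gene
    true_slope_sign: np.ndarray      # per gene, in {-1, 0, +1}
    archetype_signature: np.ndarray | None = None  # per gene, "" or owning archetype

    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "latent_time": self.latent_time,
                "population_label": self.population_label,
                "is_low_count": self.is_low_count,
                "is_low_actb": self.is_low_actb,
                "s_phase": self.s_phase,
                "library_size": self.library_size,
            }
        )

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "program_membership": self.program_membership,
                "true_slope_sign": self.true_slope_sign,
                "archetype_signature": (
                    self.archetype_signature
                    if self.archetype_signature is not None
                    else [""] * len(self.gene_ids)
                ),
            }
        )


def _well_name(i: int) -> str:
    row = "ABCDEFGHIJKLMNOP"[(i % WELLS_PER_PLATE) // 24]
    col = (i % WELLS_PER_PLATE) % 24 + 1
    return f"{row}{col:02d}"


def _gene_programs(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic block layout: Actb, planted programs, background, spike-ins."""
    programs = [PROGRAM_HOUSEKEEPING]
    programs += [PROGRAM_MONOTONE_UP] * config.n_monotone_up
    programs += [PROGRAM_MONOTONE_DOWN] * config.n_monotone_down
    programs += [PROGRAM_TRANSIENT] * config.n_transient
    programs += [PROGRAM_BACKGROUND] * (config.n_genes - len(programs))
    programs += [PROGRAM_SPIKEIN] * config.n_spikeins

    gene_ids = [HOUSEKEEPING_GENE]
    gene_ids += [f"Gene{i:05d}" for i in range(1, config.n_genes)]
    gene_ids += [f"{SPIKEIN_PREFIX}{i:05d}" for i in range(1, config.n_spikeins + 1)]
    return np.array(gene_ids, dtype=object), np.array(programs, dtype=object)


def simulate_timecourse(
    config: SimConfig,
) -> tuple[RawCountMatrix, pd.DataFrame, TrajectoryTruth]:
    """Draw a full synthetic experiment.

    Returns the raw count matrix (genes x cells, spike-ins included), the
    per-cell metadata frame and the ground-truth record. Bulk/empty control
    wells are appended after the single cells so the control-removal step
    has something to remove.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids, programs = _gene_programs(config)
    n_rows = len(gene_ids)

    # log2 relative abundance at tau = 0
    base = rng.normal(4.0, 2.0, size=n_rows)
    planted = np.isin(programs, [PROGRAM_MONOTONE_UP, PROGRAM_MONOTONE_DOWN, PROGRAM_TRANSIENT])
    base[planted] = rng.normal(6.0, 1.0, size=planted.sum())
    # a third of the background is near-silent, as in real transcriptomes;
    # this also keeps the low-mean HVG bin from being dominated by the
    # bimodal archetype markers
    bg_idx = np.nonzero(programs == PROGRAM_BACKGROUND)[0]
    quiet = bg_idx[rng.random(len(bg_idx)) < 0.30]
    base[quiet] = rng.normal(-2.0, 1.5, size=len(quiet))
    # housekeeping ~6% and spike-ins ~5% of the biological mass at tau=0
    is_hk = programs == PROGRAM_HOUSEKEEPING
    is_spike = programs == PROGRAM_SPIKEIN
    bio_mass = np.exp2(base[~(is_hk | is_spike)]).sum()
    base[is_hk] = np.log2(0.06 * bio_mass)
    base[is_spike] = np.log2(0.05 * bio_mass / max(config.n_spikeins, 1))

    slope = np.zeros(n_rows)
    slope[programs == PROGRAM_MONOTONE_UP] = config.effect_size
    slope[programs == PROGRAM_MONOTONE_DOWN] = -config.effect_size
    sign = np.sign(slope).astype(int)

    bump_amp = np.where(programs == PROGRAM_TRANSIENT, config.effect_size, 0.0)

    dispersion = config.dispersion_median * np.exp(
        rng.normal(0.0, config.dispersion_log_sd, size=n_rows)
    )
    dispersion[is_hk | is_spike] = 0.05  # technical rows are low-noise

    # archetype signatures drawn from the background genes, disjoint
    background_idx = np.nonzero(programs == PROGRAM_BACKGROUND)[0]
    n_arch = config.off_trajectory_populations
    sig_total = n_arch * config.archetype_signature_size
    if sig_total > len(background_idx):
        raise ValueError("not enough background genes for archetype signatures")
    sig_pick = rng.choice(background_idx, size=sig_total, replace=False)
    archetype_shift = np.zeros((n_arch, n_rows))
    signature_owner = np.array([""] * n_rows, dtype=object)
    # signature genes are near-silent off-archetype (so detection fractions
    # differ between populations) and rise to ~2^(4+effect) on-archetype
    base[sig_pick] = rng.normal(-5.0, 0.5, size=sig_total)
    for a in range(n_arch):
        rows = sig_pick[a * config.archetype_signature_size : (a + 1) * config.archetype_signature_size]
        archetype_shift[a, rows] = (4.0 + config.archetype_effect) - base[rows]
        signature_owner[rows] = f"Archetype{a + 1}"

    # --- cells ---------------------------------------------------------
    cond_order = np.arange(config.n_conditions)
    cond_names = [f"C{i + 1:02d}" for i in cond_order]
    cells: list[dict] = []
    tau_list: list[float] = []
    pop_list: list[str] = []

    for c in cond_order:
        for _ in range(config.cells_per_condition):
            tau = config.condition_times[c] + rng.uniform(-config.time_jitter, config.time_jitter)
            tau_list.append(float(np.clip(tau, 0.0, 1.0)))
            pop_list.append(TRAJECTORY_LABEL)
            cells.append({"condition_order": int(c)})
    for a in range(n_arch):
        for j in range(config.cells_per_population):
            c = int(cond_order[j % config.n_conditions])
            tau_list.append(float(config.condition_times[c]))
            pop_list.append(f"Archetype{a + 1}")
            cells.append({"condition_order": c})

    n_cells = len(cells)
    tau = np.array(tau_list)
    pop = np.array(pop_list, dtype=object)

    counts = np.zeros((n_rows, n_cells), dtype=np.int64)
    library_size = np.zeros(n_cells, dtype=np.int64)

    if n_cells:
        libsizes = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n_cells)
        arch_index = {f"Archetype{a + 1}": a for a in range(n_arch)}
        for j in range(n_cells):
            log2mu = base.copy()
            if pop[j] == TRAJECTORY_LABEL:
                log2mu = log2mu + slope * tau[j]
                log2mu = log2mu + bump_amp * np.exp(
                    -((tau[j] - 0.5) ** 2) / (2.0 * config.transient_width**2)
                )
            else:
                log2mu = log2mu + archetype_shift[arch_index[pop[j]]]
            # spike-ins and housekeeping never vary with state
            fixed = (programs == PROGRAM_SPIKEIN) | (programs == PROGRAM_HOUSEKEEPING)
            log2mu[fixed] = base[fixed]
            weight = np.exp2(log2mu)
            mu = libsizes[j] * weight / weight.sum()
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            col = rng.poisson(lam)
            library_size[j] = col.sum()
            keep_p = 1.0 / (1.0 + np.exp(-config.dropout_steepness * (np.log2(mu + 1.0) - config.dropout_midpoint)))
            col = rng.binomial(col, keep_p)
            counts[:, j] = col

    # --- identifiers / metadata ---------------------------------------
    cell_ids = []
    plate_ids = []
    wells = []
    cond_labels = []
    cond_orders = []
    plate_of_condition: dict[tuple[int, int], str] = {}
    per_cond_counter = {c: 0 for c in cond_order}
    for j, info in enumerate(cells):
        c = info["condition_order"]
        k = per_cond_counter[c]
        per_cond_counter[c] += 1
        plate_no = k // WELLS_PER_PLATE
        plate = f"PL{c + 1:02d}{chr(ord('a') + plate_no)}"
        plate_of_condition[(c, plate_no)] = plate
        cell_ids.append(f"{plate}:{_well_name(k)}")
        plate_ids.append(plate)
        wells.append(_well_name(k))
        cond_labels.append(cond_names[c])
        cond_orders.append(int(c))

    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "plate_id": plate_ids,
            "well": wells,
            "condition": cond_labels,
            "condition_time_order": cond_orders,
            "well_type": "single_cell",
            "sort_gate": "CD45+",
        }
    )

    matrix = RawCountMatrix(counts, gene_ids, np.array(cell_ids, dtype=object))
    matrix, meta = _append_control_wells(matrix, meta, config, rng)

    n_total = matrix.n_cells
    pad = n_total - n_cells
    truth = TrajectoryTruth(
        cell_ids=matrix.cell_ids.copy(),
        latent_time=np.concatenate([tau, np.full(pad, np.nan)]),
        population_label=np.concatenate([pop, np.array(["control"] * pad, dtype=object)]),
        is_low_count=np.zeros(n_total, dtype=bool),
        is_low_actb=np.zeros(n_total, dtype=bool),
        s_phase=np.concatenate(
            [rng.random(n_cells) < config.s_phase_fraction, np.zeros(pad, dtype=bool)]
        ),
        library_size=np.concatenate([library_size, matrix.counts[:, n_cells:].sum(axis=0)]),
        gene_ids=gene_ids.copy(),
        program_membership=programs.copy(),
        true_slope_sign=sign.copy(),
        archetype_signature=signature_owner.copy(),
    )
    return matrix, meta, truth


def _append_control_wells(matrix, meta, config, rng):
    """Add bulk (deep, many-cell) and empty (near-zero) control wells."""
    n_ctrl = config.n_bulk_controls + config.n_empty_controls
    if n_ctrl == 0 or matrix.n_cells == 0:
        return matrix, meta
    n_rows = matrix.n_genes
    cols = []
    rows_meta = []
    for i in range(n_ctrl):
        is_bulk = i < config.n_bulk_controls
        well = _well_name(WELLS_PER_PLATE - 1 - i)
        plate = meta["plate_id"].iloc[0] if len(meta) else "PL01a"
        cid = f"{plate}:{well}"
        if is_bulk:
            template = matrix.counts[:, rng.integers(0, matrix.n_cells)]
            col = rng.poisson(template.astype(float) * 20.0)
        else:
            col = rng.poisson(np.full(n_rows, 0.002))
        cols.append(col)
        rows_meta.append(
            {
                "cell_id": cid,
                "plate_id": plate,
                "well": well,
                "condition": meta["condition"].iloc[0] if len(meta) else "C01",
                "condition_time_order": int(meta["condition_time_order"].iloc[0]) if len(meta) else 0,
                "well_type": "bulk_control" if is_bulk else "empty_control",
                "sort_gate": "CD45+",
            }
        )
    counts = np.concatenate([matrix.counts, np.column_stack(cols)], axis=1)
    cell_ids = np.concatenate([matrix.cell_ids, [r["cell_id"] for r in rows_meta]])
    meta = pd.concat([meta, pd.DataFrame(rows_meta)], ignore_index=True)
    return RawCountMatrix(counts, matrix.gene_ids, cell_ids), meta


def plant_qc_failures(
    matrix: RawCountMatrix,
    truth: TrajectoryTruth,
    config: SimConfig,
) -> tuple[RawCountMatrix, TrajectoryTruth]:
    """Degrade disjoint cell subsets so the QC filters have true positives.

    ``frac_low_count`` cells are binomially thinned to a total strictly below
    2^16; a disjoint ``frac_low_actb`` fraction has the housekeeping gene
    zeroed out. Truth flags are updated in place on a copy.
    """
    if config.frac_low_count + config.frac_low_actb >= 1.0:
        raise ValueError("frac_low_count + frac_low_actb must be < 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9C]))
    matrix = matrix.copy()

    eligible = np.nonzero(
        [p != "control" for p in truth.population_label]
    )[0]
    n_low = int(round(config.frac_low_count * len(eligible)))
    n_actb = int(round(config.frac_low_actb * len(eligible)))
    picked = rng.choice(eligible, size=n_low + n_actb, replace=False)
    low_count_cells = picked[:n_low]
    low_actb_cells = picked[n_low:]

    hk_row = np.nonzero(matrix.gene_ids == HOUSEKEEPING_GENE)[0]
    if hk_row.size == 0:
        raise ValueError(f"housekeeping gene {HOUSEKEEPING_GENE!r} missing")
    hk_row = hk_row[0]

    for j in low_count_cells:
        total = matrix.counts[:, j].sum()
        target = rng.integers(8192, 60000)
        if total > 0:
            matrix.counts[:, j] = rng.binomial(matrix.counts[:, j], min(1.0, target / total))
        # thinning is random; enforce the strict bound deterministically
        while matrix.counts[:, j].sum() >= 65536:
            matrix.counts[:, j] = rng.binomial(matrix.counts[:, j], 0.9)
    for j in low_actb_cells:
        matrix.counts[hk_row, j] = 0

    is_low_count = truth.is_low_count.copy()
    is_low_actb = truth.is_low_actb.copy()
    is_low_count[low_count_cells] = True
    is_low_actb[low_actb_cells] = True
    new_truth = TrajectoryTruth(
        cell_ids=truth.cell_ids.copy(),
        latent_time=truth.latent_time.copy(),
        population_label=truth.population_label.copy(),
        is_low_count=is_low_count,
        is_low_actb=is_low_actb,
        s_phase=truth.s_phase.copy(),
        library_size=truth.library_size.copy(),
        gene_ids=truth.gene_ids.copy(),
        program_membership=truth.program_membership.copy(),
        true_slope_sign=truth.true_slope_sign.copy(),
        archetype_signature=None if truth.archetype_signature is None else truth.archetype_signature.copy(),
    )
    return matrix, new_truth


def simulate_index_sort(
    metadata: pd.DataFrame,
    config: SimConfig,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    plate_shifts: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-cell fluorescence with plate-specific affine shifts.

    ``plate_shifts[plate][channel]`` adds a fixed offset, emulating voltage
    differences between sorting sessions; when None, shifts are drawn
    N(0, index_plate_shift_sd) per plate and channel.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x15]))
    plates = list(dict.fromkeys(metadata["plate_id"]))
    if plate_shifts is None:
        plate_shifts = {
            p: {ch: float(rng.normal(0.0, config.index_plate_shift_sd)) for ch in channels}
            for p in plates
        }
    base_level = {ch: 500.0 + 150.0 * i for i, ch in enumerate(channels)}
    n = len(metadata)
    out = {
        "event_id": [f"EV{i:06d}" for i in range(n)],
        "plate_id": metadata["plate_id"].to_numpy(),
        "well": metadata["well"].to_numpy(),
        "sequenced": np.ones(n, dtype=bool),
    }
    for ch in channels:
        vals = base_level[ch] + rng.normal(0.0, 60.0, size=n)
        shift = np.array([plate_shifts.get(p, {}).get(ch, 0.0) for p in out["plate_id"]])
        out[ch] = vals + shift
    return pd.DataFrame(out)


def simulate_hoechst(
    n: int,
    s_fraction: float = 0.10,
    cv: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """DNA-content intensity mixture with known S/G2-M labels.

    G0/G1 events are lognormal around a 2n mode; S/G2-M events sit at
    1.6x-2x the mode. Exactly ``round(n * s_fraction)`` events are labelled S.
    """
    if not 0.0 <= s_fraction <= 1.0:
        raise ValueError("s_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mode = 100.0
    n_s = int(round(n * s_fraction))
    labels = np.zeros(n, dtype=bool)
    labels[rng.choice(n, size=n_s, replace=False) if n else []] = True
    values = np.empty(n)
    sigma = math.log1p(cv)
    g1 = ~labels
    values[g1] = mode * np.exp(rng.normal(0.0, sigma, size=int(g1.sum())))
    factor = rng.uniform(1.6, 2.0, size=n_s)
    values[labels] = mode * factor * np.exp(rng.normal(0.0, sigma, size=n_s))
    return values, labels
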