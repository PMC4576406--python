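"""Synthetic single-cell experiment generator with full ground truth.

The generator emulates a deep-coverage microfluidic single-cell RNA-seq
study of a stem-cell compartment: per-cell library-size variation, ERCC-like
spike-ins whose squared CV across cells follows a1/mu + alpha0, planted
cell-cycle stage programs (with the canonical cyclin oscillation and
quiescence markers), planted lineage-priming programs (lymphoid,
mega-erythroid, granulocyte-macrophage) whose prevalence differs by
genotype, a knockout genotype that shifts stage occupancy toward S/G2/M,
silences the lymphoid program and scales up transcription in proliferative
cells, plus mitochondrial genes, deletion-region read counts and optional
planted QC failures.

Generative model: counts are drawn as

    k_gj ~ NB(mean = mu_gj, var = a1 * mu_gj)        (quasi-Poisson shot noise)
    mu_gj = baseline_g * 2^(stage fold) * 2^(lineage fold)
            * libsize_j * activity_j * B_gj * T_gj

with B_gj ~ Gamma(CV2 = cv2_bio_g) biological noise for highly variable
genes (1 otherwise) and T_gj ~ Gamma(CV2 = alpha0) multiplicative technical
noise shared by all rows.  Spike-ins replace baseline*folds*libsize with a
fixed pool abundance times a per-cell capture efficiency, so spike-in
size-factor normalization leaves CV2 ~= a1/mu + alpha0.  Seeded
pseudo-randomness is part of the public contract: the same config yields
byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import CellMetadata, CountMatrix, DataError, GeneSetCollection

STAGES = ("G0/early-G1", "late-G1", "S", "G2/M")
LINEAGES = ("lymphoid", "mega-erythroid", "granulocyte-macrophage")

#: stage marker genes guaranteed to exist in every simulated matrix
STAGE_MARKERS: dict[str, tuple[str, ...]] = {
    "G0/early-G1": ("Cdkn1c", "Txnip"),
    "late-G1": ("Ccnd2", "Ccne2", "Cdk2"),
    "S": ("Rrm2", "Mcm2", "Mcm5", "Mcm7", "Ccna2", "Uhrf1"),
    "G2/M": ("Ccnb2", "Cdk1", "Ccnf", "Prc1", "Plk1", "Mki67"),
}

LINEAGE_MARKERS: dict[str, tuple[str, ...]] = {
    "lymphoid": ("Bcl11a", "Dntt", "Flt3", "Il7r", "Rag1", "Rag2", "Hlf", "Mecom"),
    "mega-erythroid": ("Gfi1b", "Gata1", "Klf1", "Vwf", "Itga2b", "Epor", "Zfpm1"),
    "granulocyte-macrophage": ("Gfi1", "Cebpa", "Mpo", "Elane", "Csf1r", "Fcgr3"),
}

MITO_GENE_NAMES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Co3",
    "mt-Atp6", "mt-Atp8", "mt-Cytb", "mt-Nd3", "mt-Nd4",
)

#: default stage occupancy of the unperturbed group: cluster counts 72/14/21/10
#: normalized over the 117 cells that received a stage label
WT_OCCUPANCY = (72 / 117, 14 / 117, 21 / 117, 10 / 117)
#: knockout occupancy, shifted so S + G2/M = 0.59 (vs 0.26 in the control)
KO_OCCUPANCY = (0.33, 0.08, 0.40, 0.19)


@dataclass
class SimConfig:
    """Study conditions of a simulated experiment.

    Defaults mirror the real study layout: ~119 control and ~61 knockout
    cells, 92 spike-in species, a control stage occupancy of
    (0.605, 0.118, 0.176, 0.084) and a knockout occupancy whose S+G2/M
    fraction is 0.59.
    """

    groups: dict[str, int] = field(default_factory=lambda: {"WT": 119, "KO": 61})
    n_genes: int = 2000
    n_spikeins: int = 92
    stage_occupancy: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"WT": WT_OCCUPANCY, "KO": KO_OCCUPANCY}
    )
    #: genes per planted stage program (markers included)
    stage_program_size: int = 100
    stage_l2fc: float = 3.0
    #: extra cycle-annotated genes carrying no program
    n_null_cycle_genes: int = 200
    #: genes per planted lineage program (markers included)
    lineage_program_size: int = 40
    lineage_l2fc: float = 2.5
    n_null_hema_genes: int = 60
    lineage_prevalence: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "WT": {"lymphoid": 0.35, "mega-erythroid": 0.2, "granulocyte-macrophage": 0.2},
            "KO": {"lymphoid": 0.0, "mega-erythroid": 0.4, "granulocyte-macrophage": 0.4},
        }
    )
    #: (number of highly variable genes, biological CV) outside the programs
    n_hv_genes: int = 200
    hv_biological_cv: float = 1.0
    #: HV genes are planted at baseline means >= this (power is mean-dependent)
    hv_min_mean: float = 50.0
    #: lognormal (mean-log, sd-log) of non-program baseline means
    gene_mean_lognorm: tuple[float, float] = (np.log(150.0), 1.0)
    program_mean_lognorm: tuple[float, float] = (np.log(80.0), 0.6)
    libsize_lognorm: tuple[float, float] = (0.0, 0.25)
    spikein_pool: np.ndarray | None = None  # default: log-spaced 0.5 .. 4000
    capture_efficiency_sd: float = 0.1
    #: technical noise law planted in every row: CV2 = a1/mu + alpha0
    tech_a1: float = 2.0
    tech_alpha0: float = 0.05
    #: global mean scale-up of proliferative (S, G2/M) cells in these groups
    activity_fold: float = 1.5
    activity_groups: tuple[str, ...] = ("KO",)
    #: lymphoid program silenced in these groups regardless of prevalence
    mito_fraction_target: float = 0.04
    #: planted QC failures (fractions of cells per group)
    frac_low_depth: float = 0.0
    low_depth_scale: float = 0.02
    frac_high_mito: float = 0.0
    high_mito_fraction: float = 0.25
    frac_anomalous: float = 0.0
    #: deletion-region screen: groups carrying the deletion, leak fraction
    deletion_groups: tuple[str, ...] = ("KO",)
    deletion_locus_mean: float = 20.0
    deletion_leak_frac: float = 0.05
    deletion_leak_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, occ in self.stage_occupancy.items():
            occ = np.asarray(occ, dtype=float)
            if len(occ) != len(STAGES):
                raise DataError(f"occupancy for {g!r} must have {len(STAGES)} entries")
            if abs(occ.sum() - 1.0) > 1e-12:
                raise DataError(f"occupancy for {g!r} sums to {occ.sum()}, not 1")
            if (occ < 0).any():
                raise DataError(f"occupancy for {g!r} has negative entries")
        for g in self.groups:
            if g not in self.stage_occupancy:
                raise DataError(f"no stage occupancy for group {g!r}")
            prev = self.lineage_prevalence.get(g, {})
            if sum(prev.values()) > 1.0 + 1e-12:
                raise DataError(f"lineage prevalence for {g!r} exceeds 1")
        if self.tech_a1 < 1.0:
            raise DataError("tech_a1 must be >= 1 (shot-noise scale)")
        if self.capture_efficiency_sd <= 0:
            raise DataError("capture_efficiency_sd must be positive")


@dataclass
class SimTruth:
    """Ground truth: per-cell stage/lineage/group/scales, per-gene programs."""

    cells: pd.DataFrame
    genes: pd.DataFrame
    config: SimConfig


def _quota_labels(
    rng: np.random.Generator, labels: list[str], probs: np.ndarray, n: int
) -> np.ndarray:
    """Composition by largest-remainder quota, then shuffled.

    A group of n cells realizes the occupancy vector exactly (up to integer
    rounding), mirroring how the study conditions state composition as
    counts; only the within-group arrangement is random.
    """
    quota = probs * n
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:remainder]] += 1
    out = np.repeat(np.asarray(labels, dtype=object), counts)
    rng.shuffle(out)
    return out


def _gamma_noise(rng: np.random.Generator, cv2: float, size) -> np.ndarray:
    if cv2 <= 0:
        return np.ones(size)
    shape = 1.0 / cv2
    return rng.gamma(shape, 1.0 / shape, size=size)


def _quasi_poisson(rng: np.random.Generator, rate: np.ndarray, a1: float) -> np.ndarray:
    """Counts with mean ``rate`` and variance ``a1 * rate``."""
    if a1 <= 1.0 + 1e-12:
        return rng.poisson(rate)
    r = rate / (a1 - 1.0)
    p = 1.0 / a1
    return rng.negative_binomial(np.maximum(r, 1e-12), p)


def _build_gene_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign names, programs, baselines and biological CV2 to all genes."""
    names: list[str] = []
    stage_prog: list[str] = []
    lineage_prog: list[str] = []
    annot: list[str] = []  # cycle / hematopoietic / mito / none

    def add(name, sp="", lp="", an="none"):
        names.append(name)
        stage_prog.append(sp)
        lineage_prog.append(lp)
        annot.append(an)

    for stage in STAGES:
        markers = STAGE_MARKERS[stage]
        tag = stage.replace("/", "").replace("-", "")
        for g in markers:
            add(g, sp=stage, an="cycle")
        for i in range(max(cfg.stage_program_size - len(markers), 0)):
            add(f"Cyc{tag}_{i + 1:03d}", sp=stage, an="cycle")
    for i in range(cfg.n_null_cycle_genes):
        add(f"CycNull_{i + 1:03d}", an="cycle")
    for lin in LINEAGES:
        markers = LINEAGE_MARKERS[lin]
        tag = {"lymphoid": "Lym", "mega-erythroid": "MegE",
               "granulocyte-macrophage": "GM"}[lin]
        for g in markers:
            add(g, lp=lin, an="hematopoietic")
        for i in range(max(cfg.lineage_program_size - len(markers), 0)):
            add(f"{tag}_{i + 1:03d}", lp=lin, an="hematopoietic")
    for i in range(cfg.n_null_hema_genes):
        add(f"HemaNull_{i + 1:03d}", an="hematopoietic")
    for g in MITO_GENE_NAMES:
        add(g, an="mito")
    n_structured = len(names)
    if n_structured > cfg.n_genes:
        raise DataError(
            f"n_genes={cfg.n_genes} too small for the configured programs "
            f"({n_structured} structured genes)"
        )
    for i in range(cfg.n_genes - n_structured):
        add(f"Gene{i + 1:05d}")
    genes = pd.DataFrame(
        {
            "gene_id": names,
            "stage_program": stage_prog,
            "lineage_program": lineage_prog,
            "annotation": annot,
        }
    )
    program = (genes["stage_program"] != "") | (genes["lineage_program"] != "")
    mu_log, sd_log = cfg.gene_mean_lognorm
    baseline = rng.lognormal(mu_log, sd_log, size=cfg.n_genes)
    pm, ps = cfg.program_mean_lognorm
    baseline[program.to_numpy()] = rng.lognormal(pm, ps, size=int(program.sum()))
    mito = genes["annotation"] == "mito"
    if mito.any():
        target = cfg.mito_fraction_target
        non_mito_total = baseline[~mito.to_numpy()].sum()
        baseline[mito.to_numpy()] = (
            target / (1 - target) * non_mito_total / mito.sum()
        )
    genes["baseline_mean"] = baseline
    cv2 = np.zeros(cfg.n_genes)
    free = (~program & ~mito).to_numpy()
    eligible = np.flatnonzero(free)
    n_hv = min(cfg.n_hv_genes, len(eligible))
    hv_idx = rng.choice(eligible, size=n_hv, replace=False)
    cv2[hv_idx] = cfg.hv_biological_cv**2
    # HV power depends on expression; keep planted HV genes well expressed
    lo = baseline[hv_idx] < cfg.hv_min_mean
    if lo.any():
        baseline[hv_idx[lo]] = cfg.hv_min_mean * np.exp(
            rng.uniform(0.0, 1.5, size=int(lo.sum()))
        )
        genes["baseline_mean"] = baseline
    genes["cv2_bio"] = cv2
    genes["is_hv"] = cv2 > 0
    overlap = genes.loc[
        (genes["stage_program"] != "") & (genes["lineage_program"] != ""), "gene_id"
    ]
    if len(overlap):
        warnings.warn(f"{len(overlap)} genes belong to both a stage and a lineage program")
    return genes


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[CountMatrix, CellMetadata, SimTruth, GeneSetCollection]:
    """Draw one experiment: counts, metadata, ground truth and marker sets."""
    rng = np.random.default_rng(cfg.seed)
    genes = _build_gene_table(cfg, rng)

    # ---------------- per-cell truth -----------------------------------
    cell_rows = []
    for group, n in cfg.groups.items():
        occ = np.asarray(cfg.stage_occupancy[group], dtype=float)
        stage_labels = _quota_labels(rng, list(STAGES), occ, n)
        prev = dict(cfg.lineage_prevalence.get(group, {}))
        lin_names = list(LINEAGES)
        probs = np.array([prev.get(l, 0.0) for l in lin_names])
        probs = np.append(probs, max(1.0 - probs.sum(), 0.0))
        lin_labels = _quota_labels(
            rng, lin_names + ["none"], probs / probs.sum(), n
        )
        for i in range(n):
            cell_rows.append(
                {
                    "cell_id": f"{group}_c{i + 1:03d}",
                    "group": group,
                    "stage": stage_labels[i],
                    "lineage": lin_labels[i],
                }
            )
    cells = pd.DataFrame(cell_rows)
    n_cells = len(cells)
    ml, sl = cfg.libsize_lognorm
    cells["libsize"] = rng.lognormal(ml, sl, size=n_cells)
    cells["capture_eff"] = rng.lognormal(0.0, cfg.capture_efficiency_sd, size=n_cells)
    proliferative = cells["stage"].isin(["S", "G2/M"])
    boosted = proliferative & cells["group"].isin(cfg.activity_groups)
    cells["activity_scale"] = np.where(boosted, cfg.activity_fold, 1.0)

    # planted QC failures ------------------------------------------------
    cells["planted_low_depth"] = False
    cells["planted_high_mito"] = False
    cells["planted_anomalous"] = False
    for group in cfg.groups:
        idx = cells.index[cells["group"] == group].to_numpy()
        pool = idx.copy()
        for frac, col in (
            (cfg.frac_low_depth, "planted_low_depth"),
            (cfg.frac_high_mito, "planted_high_mito"),
            (cfg.frac_anomalous, "planted_anomalous"),
        ):
            n_fail = int(round(frac * len(idx)))
            if n_fail and len(pool):
                chosen = rng.choice(pool, size=min(n_fail, len(pool)), replace=False)
                cells.loc[chosen, col] = True
                pool = np.setdiff1d(pool, chosen)
    cells.loc[cells["planted_low_depth"], "libsize"] *= cfg.low_depth_scale

    # ---------------- mean matrix --------------------------------------
    base = genes["baseline_mean"].to_numpy()
    n_genes = cfg.n_genes
    fold = np.ones((n_genes, n_cells))
    stage_arr = cells["stage"].to_numpy()
    lin_arr = cells["lineage"].to_numpy()
    for stage in STAGES:
        gmask = (genes["stage_program"] == stage).to_numpy()
        cmask = stage_arr == stage
        fold[np.ix_(gmask, cmask)] *= 2.0**cfg.stage_l2fc
    for lin in LINEAGES:
        gmask = (genes["lineage_program"] == lin).to_numpy()
        cmask = lin_arr == lin
        fold[np.ix_(gmask, cmask)] *= 2.0**cfg.lineage_l2fc
    mu = (
        base[:, None]
        * fold
        * cells["libsize"].to_numpy()[None, :]
        * cells["activity_scale"].to_numpy()[None, :]
    )
    # boost mito rows of planted high-mito cells to the target failure level
    mito_mask = (genes["annotation"] == "mito").to_numpy()
    if cells["planted_high_mito"].any() and mito_mask.any():
        m0 = cfg.mito_fraction_target
        m1 = cfg.high_mito_fraction
        factor = m1 * (1 - m0) / (m0 * (1 - m1))
        cmask = cells["planted_high_mito"].to_numpy()
        mu[np.ix_(mito_mask, cmask)] *= factor

    # biological and technical multiplicative noise ----------------------
    cv2_bio = genes["cv2_bio"].to_numpy()
    hv = cv2_bio > 0
    if hv.any():
        shapes = 1.0 / cv2_bio[hv]
        mu[hv] *= rng.gamma(
            shapes[:, None], 1.0 / shapes[:, None], size=(int(hv.sum()), n_cells)
        )
    if cfg.tech_alpha0 > 0:
        mu *= _gamma_noise(rng, cfg.tech_alpha0, mu.shape)
    counts_bio = _quasi_poisson(rng, mu, cfg.tech_a1)

    # ---------------- spike-ins -----------------------------------------
    pool = (
        np.asarray(cfg.spikein_pool, dtype=float)
        if cfg.spikein_pool is not None
        else np.geomspace(0.5, 4000.0, cfg.n_spikeins)
    )
    if len(pool) != cfg.n_spikeins:
        raise DataError("spikein_pool length must equal n_spikeins")
    smu = pool[:, None] * cells["capture_eff"].to_numpy()[None, :]
    if cfg.tech_alpha0 > 0:
        smu = smu * _gamma_noise(rng, cfg.tech_alpha0, smu.shape)
    counts_spike = _quasi_poisson(rng, smu, cfg.tech_a1)

    # ---------------- assemble outputs ----------------------------------
    spike_ids = [f"ERCC-{i + 1:05d}" for i in range(cfg.n_spikeins)]
    gene_ids = np.concatenate([genes["gene_id"].to_numpy(), spike_ids])
    counts = np.vstack([counts_bio, counts_spike])
    is_spike = np.concatenate(
        [np.zeros(n_genes, dtype=bool), np.ones(cfg.n_spikeins, dtype=bool)]
    )
    is_mito = np.concatenate([mito_mask, np.zeros(cfg.n_spikeins, dtype=bool)])
    matrix = CountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cells["cell_id"].to_numpy(),
        is_spikein=is_spike,
        is_mito=is_mito,
    )

    # deletion-region evidence and capture flags
    del_count = np.zeros(n_cells, dtype=int)
    leak = np.zeros(n_cells, dtype=bool)
    for group in cfg.groups:
        cmask = (cells["group"] == group).to_numpy()
        if group in cfg.deletion_groups:
            gidx = np.flatnonzero(cmask)
            n_leak = int(round(cfg.deletion_leak_frac * len(gidx)))
            if n_leak:
                chosen = rng.choice(gidx, size=n_leak, replace=False)
                leak[chosen] = True
                del_count[chosen] = 1 + rng.poisson(cfg.deletion_leak_mean, size=n_leak)
        else:
            del_count[cmask] = rng.poisson(cfg.deletion_locus_mean, size=int(cmask.sum()))
    cells["planted_incomplete_deletion"] = leak
    capture = np.where(cells["planted_anomalous"], "anomalous", "single")
    meta = CellMetadata(
        table=pd.DataFrame(
            {
                "cell_id": cells["cell_id"],
                "group": cells["group"],
                "deletion_region_count": del_count,
                "capture_flag": capture,
            }
        )
    )

    # realized QC metrics as independent truth (plain arithmetic)
    bio_counts = counts_bio
    cells["true_total_counts"] = bio_counts.sum(axis=0)
    cells["true_genes_detected"] = (bio_counts > 0).sum(axis=0)
    mito_tot = bio_counts[mito_mask].sum(axis=0)
    with np.errstate(invalid="ignore"):
        cells["true_mito_fraction"] = np.where(
            cells["true_total_counts"] > 0,
            mito_tot / np.maximum(cells["true_total_counts"], 1),
            0.0,
        )

    gene_sets = _emit_gene_sets(genes)
    genes_out = genes.set_index("gene_id", drop=False)
    truth = SimTruth(cells=cells.set_index("cell_id", drop=False), genes=genes_out, config=cfg)
    return matrix, meta, truth, gene_sets


def _emit_gene_sets(genes: pd.DataFrame) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    sets["cell_cycle"] = list(genes.loc[genes["annotation"] == "cycle", "gene_id"])
    desc["cell_cycle"] = "planted cycle-annotated genes (programs + nulls)"
    sets["hematopoietic"] = list(
        genes.loc[genes["annotation"] == "hematopoietic", "gene_id"]
    )
    desc["hematopoietic"] = "planted hematopoietic genes (lineage programs + nulls)"
    for stage in STAGES:
        key = "stage_" + stage.replace("/", "_").replace("-", "_")
        sets[key] = list(genes.loc[genes["stage_program"] == stage, "gene_id"])
        desc[key] = f"planted {stage} program"
    lin_keys = {
        "lymphoid": "CLP_signature",
        "mega-erythroid": "MegE_signature",
        "granulocyte-macrophage": "GM_signature",
    }
    for lin, key in lin_keys.items():
        sets[key] = list(genes.loc[genes["lineage_program"] == lin, "gene_id"])
        desc[key] = f"planted {lin} lineage program"
    return GeneSetCollection(sets=sets, descriptions=desc)


# ---------------------------------------------------------------------------
# Convenience configurations


def default_config(seed: int = 0, **overrides) -> SimConfig:
    return replace(SimConfig(seed=seed), **overrides)


def technical_null_config(
    n_cells: int = 100, n_genes: int = 2000, seed: int = 0, **overrides
) -> SimConfig:
    """Pure technical noise: one group, one stage, no programs, no HV genes.

    Gene means are drawn lognormal with sd-log 1.0 around 150, so nearly all
    genes sit in the regime where the asymptotic technical CV2 dominates.
    """
    base = SimConfig(
        groups={"WT": n_cells},
        n_genes=n_genes,
        stage_occupancy={"WT": (1.0, 0.0, 0.0, 0.0)},
        stage_program_size=0,
        stage_l2fc=0.0,
        n_null_cycle_genes=0,
        lineage_program_size=0,
        lineage_l2fc=0.0,
        n_null_hema_genes=0,
        lineage_prevalence={"WT": {}},
        n_hv_genes=0,
        activity_groups=(),
        deletion_groups=(),
        seed=seed,
    )
    return replace(base, **overrides)


def stage_recovery_config(
    n_cells: int = 300, seed: int = 0, **overrides
) -> SimConfig:
    """Single-group run sized for cell-cycle stage recovery checks.

    300 cells at the control occupancy, a 600-gene cycle list (four
    150-gene stage programs plus no extra nulls), no lineage structure.
    """
    base = SimConfig(
        groups={"WT": n_cells},
        n_genes=1200,
        stage_occupancy={"WT": WT_OCCUPANCY},
        stage_program_size=150,
        n_null_cycle_genes=0,
        lineage_program_size=0,
        n_null_hema_genes=0,
        lineage_prevalence={"WT": {}},
        n_hv_genes=100,
        activity_groups=(),
        deletion_groups=(),
        seed=seed,
    )
    return replace(base, **overrides)
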