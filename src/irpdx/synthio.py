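"""Synthetic fixtures with the statistical structure each pipeline stage assumes.

Every generator is driven by a single :class:`SynthConfig` and a global
seed.  The seed expands into independent per-artifact streams through a
documented counter scheme: artifact ``k`` uses
``numpy.random.default_rng(SeedSequence(seed, spawn_key=(k,)))`` with the
artifact ids in :data:`ARTIFACT_IDS`.  A fixed seed therefore yields
byte-identical artifacts across runs and platforms (NumPy PCG64 streams).

Generators emit ground-truth labels sufficient to score every downstream
stage (species labels, planted cell states, variant filter classes, mask
geometry, planted synergy), and writers place that truth in sidecar TSVs
next to fixtures kept in standard formats (MTX + TSV, variant TSV,
16-bit TIFF, dose CSV).

Counts are negative-binomial with per-gene dispersion drawn log-normally,
matching the overdispersion single-cell analyses assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import tifffile
import yaml
from anndata import AnnData
from scipy.io import mmread, mmwrite

from .morpho import SlideMasks
from .pharmaco import DoseGrid, HillFit, loewe_surface
from .somatic import VariantTable

ARTIFACT_IDS = {
    "dual_species": 0,
    "state_mixture": 1,
    "variants": 2,
    "masks": 3,
    "dose_response": 4,
    "diff_tables": 5,
    "dgi": 6,
}

STATES = ("AC-like", "MES-like", "NSC-ciliated", "NPC-like")
CONDITIONS = ("primary", "induced", "recurrent")
PATIENTS = ("GBM39", "GBM67")

DEFAULT_PROPORTIONS = {
    "primary": {"AC-like": 0.50, "MES-like": 0.15, "NSC-ciliated": 0.0, "NPC-like": 0.35},
    "induced": {"AC-like": 0.40, "MES-like": 0.30, "NSC-ciliated": 0.10, "NPC-like": 0.20},
    "recurrent": {"AC-like": 0.20, "MES-like": 0.50, "NSC-ciliated": 0.15, "NPC-like": 0.15},
}


@dataclass
class MaskGeometry:
    """Geometry of the synthetic slide: a tissue disk containing a tumour
    core disk plus satellite islands at given centre distances (all µm)."""

    um_per_px: float = 1.0
    tissue_radius_um: float = 1500.0
    core_radius_um: float = 500.0
    # (radius_um, centre distance from core centre, angle degrees)
    satellites: tuple = ((50.0, 800.0, 0.0), (60.0, 1000.0, 120.0), (150.0, 760.0, 240.0))
    n_positive_cells: int = 200

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.tissue_radius_um <= 0 or self.core_radius_um <= 0:
            raise ValueError("radii must be positive")
        for r, d, _ in self.satellites:
            if r <= 0 or d < 0:
                raise ValueError("satellite radii/distances must be positive")
            if d + r > self.tissue_radius_um:
                raise ValueError(
                    f"satellite (r={r}, d={d}) lies outside the tissue disk"
                )


@dataclass
class SynthConfig:
    """Parameters of every synthetic artifact; ``seed`` fully determines them."""

    seed: int = 0

    # dual-species mixture
    n_cells: int = 2000
    contamination_rate: float = 0.10
    human_mean: float = 5000.0
    ambient_frac: float = 0.008
    nb_size: float = 20.0

    # cell-state mixture
    n_genes: int = 1000
    n_marker_genes: int = 60
    cells_per_condition: int = 350
    de_effect: float = 2.0
    cycle_effect: float = 0.0
    cycle_fractions: dict = field(
        default_factory=lambda: {"G1": 0.70, "S": 0.15, "G2M": 0.15}
    )
    state_proportions: dict = field(default_factory=lambda: {
        c: dict(p) for c, p in DEFAULT_PROPORTIONS.items()
    })
    replicates: int = 2
    marker_blocks: dict | None = None

    # variant calls
    purity: dict = field(default_factory=lambda: {"P": 0.8, "IR": 0.6, "R": 0.7})
    clone_counts: dict = field(
        default_factory=lambda: {"trunk": 30, "P+IR": 10, "P": 4, "IR": 4, "R": 8}
    )
    depth_mean: float = 100.0
    clonal_vaf: float = 0.5

    # slide masks
    mask_geometry: MaskGeometry = field(default_factory=MaskGeometry)

    # dose response
    hill_params: dict = field(default_factory=lambda: {
        "MBZ": (100.0, 5.0, 120.0, 1.5),
        "TMZ": (100.0, 10.0, 900.0, 1.2),
    })
    doses: dict = field(default_factory=lambda: {
        "MBZ": [0.0, 10.0, 50.0, 100.0, 250.0, 500.0],
        "TMZ": [0.0, 250.0, 500.0, 1000.0, 1500.0, 3000.0],
    })
    synergy_offset: float = 15.0
    dose_noise_sd: float = 0.5
    dose_replicates: int = 3

    # differential tables
    n_de_genes: int = 5000
    n_truth_sig: int = 500
    capture_expr: float = 0.6
    capture_meth: float = 0.3
    n_model_only: int = 200

    def __post_init__(self) -> None:
        if not np.isfinite(self.contamination_rate) or not 0 <= self.contamination_rate <= 1:
            raise ValueError("contamination_rate must be a fraction in [0, 1]")
        if self.n_cells < 10:
            raise ValueError("n_cells must be at least 10")
        for cond, props in self.state_proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"state proportions for {cond!r} sum to {total}, not 1")
            if any(p < 0 for p in props.values()):
                raise ValueError("state proportions must be non-negative")
        for s, p in self.purity.items():
            if not 0 < p <= 1:
                raise ValueError(f"purity for {s!r} must be in (0, 1], got {p}")
        for drug, (e0, einf, ec50, h) in self.hill_params.items():
            if ec50 <= 0 or h <= 0:
                raise ValueError(f"hill parameters for {drug!r} need EC50 > 0 and h > 0")
        for drug, doses in self.doses.items():
            d = np.asarray(doses, dtype=float)
            if (d < 0).any() or (np.diff(d) <= 0).any():
                raise ValueError(f"doses for {drug!r} must be non-negative and increasing")
        if isinstance(self.mask_geometry, dict):
            self.mask_geometry = MaskGeometry(**self.mask_geometry)
        if self.marker_blocks is not None:
            seen: set[int] = set()
            for state, idx in self.marker_blocks.items():
                block = set(idx)
                if block & seen:
                    raise ValueError(f"marker block for {state!r} overlaps another block")
                seen |= block

    def rng(self, artifact: str) -> np.random.Generator:
        """Per-artifact child stream (documented counter scheme)."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(ARTIFACT_IDS[artifact],))
        )

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# dual-species mixture


def gen_dual_species_counts(config: SynthConfig) -> pd.DataFrame:
    """Per-cell human/mouse aligned-read counts with ground-truth species.

    Human cells draw human counts from a negative binomial around
    ``human_mean`` and mouse counts as an ambient binomial fraction of
    them (so mouse <= human by construction); planted mouse contaminants
    are the mirror image.  Cluster labels place contaminants in their own
    cluster so the cluster-level ratio filter can be exercised.
    """
    rng = config.rng("dual_species")
    n = config.n_cells
    is_mouse = rng.random(n) < config.contamination_rate
    mean, size = config.human_mean, config.nb_size
    own = rng.poisson(rng.gamma(size, mean / size, n))
    own = np.maximum(own, 1)
    other = rng.binomial(own, config.ambient_frac)
    counts_human = np.where(is_mouse, other, own)
    counts_mouse = np.where(is_mouse, own, other)
    cluster = np.where(is_mouse, 2, rng.integers(0, 2, n))
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(n)],
            "counts_human": counts_human,
            "counts_mouse": counts_mouse,
            "cluster_id": cluster,
            "species": np.where(is_mouse, "mouse", "human"),
        }
    )


# ---------------------------------------------------------------------------
# cell-state mixture


def marker_block_layout(config: SynthConfig) -> dict[str, np.ndarray]:
    """Disjoint marker-gene index blocks per state (and cycle phases)."""
    if config.marker_blocks is not None:
        return {k: np.asarray(sorted(v)) for k, v in config.marker_blocks.items()}
    m = config.n_marker_genes
    blocks = {}
    start = 0
    names = list(STATES) + (["S", "G2M"] if config.cycle_effect > 0 else [])
    for name in names:
        blocks[name] = np.arange(start, start + m)
        start += m
    if start > config.n_genes:
        raise ValueError("marker blocks exceed the gene count")
    return blocks


def gen_state_mixture_counts(config: SynthConfig) -> AnnData:
    """Gene-by-cell counts with planted cell states across conditions.

    Negative-binomial counts (per-gene log-normal baseline mean and
    dispersion); each state over-expresses its disjoint marker block by
    ``2**de_effect``.  The ciliated state has proportion 0 in primary and
    > 0 in induced/recurrent conditions by default.  Ground-truth state
    (and cycle phase, when ``cycle_effect > 0``) labels are kept in
    ``obs``.
    """
    rng = config.rng("state_mixture")
    blocks = marker_block_layout(config)
    n_genes = config.n_genes
    base_mean = rng.lognormal(mean=np.log(2.0), sigma=1.0, size=n_genes)
    theta = rng.lognormal(mean=np.log(10.0), sigma=0.5, size=n_genes)

    obs_rows = []
    count_rows = []
    phases = list(config.cycle_fractions)
    phase_p = np.array([config.cycle_fractions[p] for p in phases])
    phase_p = phase_p / phase_p.sum()
    for patient in PATIENTS:
        for cond in CONDITIONS:
            props = config.state_proportions[cond]
            states = [s for s in STATES if props.get(s, 0) > 0]
            p = np.array([props[s] for s in states])
            p = p / p.sum()
            n_cond = config.cells_per_condition
            state_draw = rng.choice(len(states), size=n_cond, p=p)
            replicate = 1 + (np.arange(n_cond) % config.replicates)
            if config.cycle_effect > 0:
                phase_draw = rng.choice(len(phases), size=n_cond, p=phase_p)
            else:
                phase_draw = np.zeros(n_cond, dtype=int)
            mu = np.tile(base_mean, (n_cond, 1))
            for si, s in enumerate(states):
                mask = state_draw == si
                mu[np.ix_(mask, blocks[s])] *= 2.0**config.de_effect
            if config.cycle_effect > 0:
                for pi, ph in enumerate(phases):
                    if ph in blocks:
                        mask = phase_draw == pi
                        mu[np.ix_(mask, blocks[ph])] *= 2.0**config.cycle_effect
            lam = rng.gamma(theta, mu / theta)
            counts = rng.poisson(lam)
            count_rows.append(counts)
            for i in range(n_cond):
                obs_rows.append(
                    (
                        f"{patient}_{cond}_r{replicate[i]}_c{i:04d}",
                        patient,
                        cond,
                        f"r{replicate[i]}",
                        states[state_draw[i]],
                        phases[phase_draw[i]] if config.cycle_effect > 0 else "G1",
                    )
                )
    X = sp.csr_matrix(np.vstack(count_rows))
    obs = pd.DataFrame(
        obs_rows, columns=["cell_id", "patient", "condition", "replicate", "state", "phase"]
    ).set_index("cell_id")
    var = pd.DataFrame(index=[f"G{i:04d}" for i in range(n_genes)])
    var["marker_block"] = ""
    for name, idx in blocks.items():
        var.iloc[idx, var.columns.get_loc("marker_block")] = name
    adata = AnnData(X=X, obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    adata.uns["truth"] = {
        "marker_blocks": {k: v.tolist() for k, v in blocks.items()},
        "de_effect": config.de_effect,
        "cycle_effect": config.cycle_effect,
    }
    return adata


# ---------------------------------------------------------------------------
# variant calls


VIOLATION_PLAN = (
    # (name, expected_stage, expected_rule)
    ("viol_flag", "candidate", "caller_flag_not_PASS"),
    ("viol_low_depth", "candidate", "tumour_depth_lt_10"),
    ("viol_low_nv", "candidate", "tumour_variant_reads_lt_3"),
    ("viol_normal_contam", "candidate", "normal_variant_reads_gt_0"),
    ("viol_low_nr", "joint", "NR_not_gt_10_in_all_samples"),
    ("viol_low_gq", "joint", "GQ_not_gt_10_in_all_samples"),
    ("viol_low_vafadj", "vafadj", "max_vafadj_below_threshold"),
)


def gen_variant_calls(config: SynthConfig) -> tuple[VariantTable, pd.DataFrame]:
    """Multi-sample variant calls with planted clonal structure and
    one deterministic violation of each filter rule.

    The clonal history is ``((P, IR), R)``: trunk mutations in all tumour
    samples, a shared P+IR clade, and private mutations.  Passing variants
    draw read counts binomially around VAF x purity at ~``depth_mean``
    coverage; violation variants are constructed with exact counts so
    their ground-truth labels are certain.  Returns the table and a truth
    frame (variant_id, clade or violation class, expected stage/rule).
    """
    samples = list(config.purity)
    if len(samples) < 2:
        raise ValueError("need at least two tumour samples")
    rng = config.rng("variants")
    normal = "Normal"
    clade_members = {
        "trunk": samples,
        "P+IR": [s for s in samples if s in ("P", "IR")],
        "P": ["P"] if "P" in samples else samples[:1],
        "IR": ["IR"] if "IR" in samples else samples[1:2],
        "R": ["R"] if "R" in samples else samples[-1:],
    }
    bases = np.array(list("ACGT"))
    rows, truth = [], []
    pos = 10_000

    def add_variant(vid_pos, flag, per_sample):
        ref, alt = rng.choice(4, size=2, replace=False)
        for s, (nr, nv, gt, gq) in per_sample.items():
            rows.append(("chr1", vid_pos, bases[ref], bases[alt], s, nr, nv, gt, gq, flag))
        return f"chr1:{vid_pos}:{bases[ref]}>{bases[alt]}"

    for clade, count in config.clone_counts.items():
        members = clade_members.get(clade)
        if members is None:
            raise ValueError(f"unknown clade {clade!r}")
        for _ in range(count):
            pos += 1000
            per_sample = {}
            for s in samples:
                nr = int(max(20, rng.poisson(config.depth_mean)))
                if s in members:
                    nv = int(rng.binomial(nr, config.clonal_vaf * config.purity[s]))
                    nv = max(nv, 3)
                    per_sample[s] = (nr, nv, "0/1", 60)
                else:
                    per_sample[s] = (nr, 0, "0/0", 60)
            per_sample[normal] = (int(max(20, rng.poisson(config.depth_mean))), 0, "0/0", 60)
            vid = add_variant(pos, "PASS", per_sample)
            truth.append((vid, clade, "passed", ""))

    first, second = samples[0], samples[1] if len(samples) > 1 else samples[0]
    for name, stage, rule in VIOLATION_PLAN:
        pos += 1000
        per_sample = {s: (100, 0, "0/0", 60) for s in samples}
        per_sample[normal] = (100, 0, "0/0", 60)
        flag = "PASS"
        if name == "viol_flag":
            per_sample[first] = (100, 30, "0/1", 60)
            flag = "badReads"
        elif name == "viol_low_depth":
            for s in samples:
                per_sample[s] = (8, 3, "0/1", 60)
        elif name == "viol_low_nv":
            for s in samples:
                per_sample[s] = (100, 2, "0/1", 60)
        elif name == "viol_normal_contam":
            per_sample[first] = (100, 30, "0/1", 60)
            per_sample[normal] = (100, 2, "0/0", 60)
        elif name == "viol_low_nr":
            per_sample[first] = (100, 30, "0/1", 60)
            per_sample[second] = (10, 0, "0/0", 60)
        elif name == "viol_low_gq":
            per_sample[first] = (100, 30, "0/1", 60)
            per_sample[second] = (100, 0, "0/0", 5)
        elif name == "viol_low_vafadj":
            for s in samples:
                per_sample[s] = (300, 5, "0/1", 60)
        vid = add_variant(pos, flag, per_sample)
        truth.append((vid, name, stage, rule))

    calls = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sample", "NR", "NV", "GT", "GQ", "flag"]
    )
    table = VariantTable(calls=calls, normal=normal, purity=dict(config.purity))
    truth_df = pd.DataFrame(
        truth, columns=["variant_id", "clade", "expected_stage", "expected_rule"]
    )
    return table, truth_df


# ---------------------------------------------------------------------------
# slide masks


def _disk(shape, center, radius_px) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def gen_masks(config: SynthConfig) -> SlideMasks:
    """Tissue disk with a tumour core and satellite islands.

    Analytic areas and expected morphometry behaviour of every satellite
    (removed from core? merged into the core's gross component?) are
    recorded in ``truth``.
    """
    geom = config.mask_geometry
    scale = geom.um_per_px
    r_tis = geom.tissue_radius_um / scale
    size = int(np.ceil(2 * r_tis)) + 9
    center = (size // 2, size // 2)
    tissue = _disk((size, size), center, r_tis)
    tumour = _disk((size, size), center, geom.core_radius_um / scale)
    sat_truth = []
    for r_um, d_um, ang in geom.satellites:
        theta = np.deg2rad(ang)
        cy = center[0] + (d_um / scale) * np.sin(theta)
        cx = center[1] + (d_um / scale) * np.cos(theta)
        tumour |= _disk((size, size), (cy, cx), r_um / scale)
        gap = d_um - geom.core_radius_um - r_um
        sat_truth.append(
            {
                "radius_um": r_um,
                "distance_um": d_um,
                "area_um2": np.pi * r_um**2,
                "removed_from_core": np.pi * r_um**2 < 10_000.0,
                "merges_with_core": gap < 150.0,
            }
        )
    rng = config.rng("masks")
    ys, xs = np.nonzero(tumour)
    take = rng.choice(len(ys), size=min(geom.n_positive_cells, len(ys)), replace=False)
    centroids = np.column_stack([ys[take], xs[take]]).astype(float)
    truth = {
        "tissue_area_um2": np.pi * geom.tissue_radius_um**2,
        "core_area_um2": np.pi * geom.core_radius_um**2,
        "satellites": sat_truth,
        "um_per_px": scale,
    }
    return SlideMasks(
        tissue=tissue, tumour=tumour, um_per_px=scale, centroids=centroids, truth=truth
    )


# ---------------------------------------------------------------------------
# dose response


def gen_dose_response(config: SynthConfig) -> DoseGrid:
    """Hill-model dose-response grid with known Loewe synergy.

    Monotherapy cells follow the Hill model exactly (plus measurement
    noise); combination cells equal the Loewe expectation minus
    ``synergy_offset`` % control (positive offset = synergy: viability
    below additivity), plus noise.  The noise-free expected surface and
    the planted offset are kept in ``truth``.
    """
    (drug_a, drug_b) = list(config.hill_params)[:2]
    fit_a = HillFit(*config.hill_params[drug_a])
    fit_b = HillFit(*config.hill_params[drug_b])
    doses_a = np.asarray(config.doses[drug_a], dtype=float)
    doses_b = np.asarray(config.doses[drug_b], dtype=float)
    expected = loewe_surface(fit_a, fit_b, doses_a, doses_b)
    combo = (doses_a[:, None] > 0) & (doses_b[None, :] > 0)
    clean = expected - config.synergy_offset * combo
    rng = config.rng("dose_response")
    noise = rng.normal(0.0, config.dose_noise_sd, size=(config.dose_replicates,) + clean.shape)
    viability = clean[None] + noise
    return DoseGrid(
        doses_a=doses_a,
        doses_b=doses_b,
        viability=viability,
        drug_a=drug_a,
        drug_b=drug_b,
        truth={
            "synergy_offset": config.synergy_offset,
            "expected": expected,
            "hill_params": dict(config.hill_params),
        },
    )


# ---------------------------------------------------------------------------
# differential tables


def gen_diff_tables(config: SynthConfig) -> dict[str, pd.DataFrame]:
    """Expression and methylation DiffTables with planted capture fractions.

    The truth contrast has ``n_truth_sig`` significant genes; each enters
    the model contrast's significant set independently with probability
    ``capture_expr`` (``capture_meth`` for methylation), with matching
    effect sign, plus ``n_model_only`` model-only significant genes.
    Truth membership is recorded in a ``planted`` column.
    """
    rng = config.rng("diff_tables")
    genes = np.array([f"GENE{i:04d}" for i in range(config.n_de_genes)])
    out = {}
    for omic, capture, eff_scale in (
        ("expr", config.capture_expr, 2.0),
        ("meth", config.capture_meth, 0.3),
    ):
        perm = rng.permutation(config.n_de_genes)
        sig_idx = perm[: config.n_truth_sig]
        extra_idx = perm[config.n_truth_sig : config.n_truth_sig + config.n_model_only]
        signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
        magnitude = np.abs(rng.normal(eff_scale, eff_scale / 4, size=config.n_de_genes))
        effect = signs * magnitude
        for role in ("truth", "model"):
            padj = rng.uniform(0.05, 1.0, size=config.n_de_genes)
            planted = np.zeros(config.n_de_genes, dtype=bool)
            if role == "truth":
                chosen = sig_idx
            else:
                captured = sig_idx[rng.random(config.n_truth_sig) < capture]
                chosen = np.concatenate([captured, extra_idx])
            padj[chosen] = rng.uniform(1e-6, 0.049, size=len(chosen))
            planted[chosen] = True
            eff = effect + rng.normal(0, eff_scale / 20, size=config.n_de_genes)
            out[f"{omic}_{role}"] = pd.DataFrame(
                {
                    "gene": genes,
                    "effect": eff,
                    "p": padj,
                    "padj": padj,
                    "contrast": f"{omic}_{role}",
                    "planted": planted,
                }
            )
    return out


def gen_dgi_table(genes: list[str], rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Local drug-gene interaction snapshot mapping some genes to drugs."""
    rng = rng or np.random.default_rng(ARTIFACT_IDS["dgi"])
    rows = []
    for i, g in enumerate(genes):
        if i % 2 == 0:
            rows.append((g, f"drug_{i // 2:02d}", "inhibitor"))
    return pd.DataFrame(rows, columns=["gene", "drug", "interaction"])


# ---------------------------------------------------------------------------
# writers / readers (standard formats + truth sidecars)


def write_dual_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_dual_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_state_matrix(adata: AnnData, outdir) -> None:
    """MTX (genes x cells) + features/barcodes TSV + truth sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.layers.get("counts", adata.X)
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(X.T), field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(outdir / "truth_cells.tsv", sep="\t")
    adata.var.to_csv(outdir / "truth_genes.tsv", sep="\t")


def read_state_matrix(outdir) -> AnnData:
    outdir = Path(outdir)
    X = sp.csr_matrix(mmread(str(outdir / "matrix.mtx")).T)
    features = pd.read_csv(outdir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=barcodes.astype(str))
    truth_cells = outdir / "truth_cells.tsv"
    if truth_cells.exists():
        obs = pd.read_csv(truth_cells, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    var = pd.DataFrame(index=features.astype(str))
    truth_genes = outdir / "truth_genes.tsv"
    if truth_genes.exists():
        var = pd.read_csv(truth_genes, sep="\t", index_col=0)
        var.index = var.index.astype(str)
        var = var.fillna("")
    adata = AnnData(X=X, obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    return adata


def write_variant_calls(table: VariantTable, truth: pd.DataFrame, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.calls[
        ["chrom", "pos", "ref", "alt", "sample", "NR", "NV", "GT", "GQ", "flag"]
    ].to_csv(outdir / "variants.tsv", sep="\t", index=False)
    purity = pd.DataFrame(
        {"sample": list(table.purity), "purity": list(table.purity.values())}
    )
    purity.to_csv(outdir / "purity.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)


def read_variant_calls(outdir, normal: str = "Normal") -> VariantTable:
    outdir = Path(outdir)
    calls = pd.read_csv(outdir / "variants.tsv", sep="\t", dtype={"chrom": str, "GT": str, "flag": str})
    purity = pd.read_csv(outdir / "purity.tsv", sep="\t")
    return VariantTable(
        calls=calls, normal=normal, purity=dict(zip(purity["sample"], purity["purity"]))
    )


def write_masks(masks: SlideMasks, outdir) -> None:
    """16-bit TIFF masks + centroid CSV + scale/truth YAML sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "tissue.tif", masks.tissue.astype(np.uint16) * 65535)
    tifffile.imwrite(outdir / "tumour.tif", masks.tumour.astype(np.uint16) * 65535)
    pd.DataFrame(masks.centroids, columns=["row", "col"]).to_csv(
        outdir / "centroids.csv", index=False
    )
    meta = {"um_per_px": float(masks.um_per_px)}
    truth = masks.truth
    if truth:
        meta["truth"] = {
            "tissue_area_um2": float(truth["tissue_area_um2"]),
            "core_area_um2": float(truth["core_area_um2"]),
            "satellites": [
                {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v)) for k, v in s.items()}
                for s in truth["satellites"]
            ],
        }
    with open(outdir / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_masks(outdir) -> SlideMasks:
    outdir = Path(outdir)
    with open(outdir / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    tissue = tifffile.imread(outdir / "tissue.tif") > 0
    tumour = tifffile.imread(outdir / "tumour.tif") > 0
    centroids = pd.read_csv(outdir / "centroids.csv").to_numpy(dtype=float)
    return SlideMasks(
        tissue=tissue,
        tumour=tumour,
        um_per_px=float(meta["um_per_px"]),
        centroids=centroids,
        truth=meta.get("truth", {}),
    )


def write_dose_grid(grid: DoseGrid, outdir) -> None:
    """One CSV per replicate; first row/column hold the doses."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in range(grid.viability.shape[0]):
        df = pd.DataFrame(grid.viability[r], index=grid.doses_a, columns=grid.doses_b)
        df.index.name = f"{grid.drug_a}\\{grid.drug_b}"
        df.to_csv(outdir / f"viability_rep{r + 1}.csv")


def read_dose_grid(outdir, drug_a: str = "drug_a", drug_b: str = "drug_b") -> DoseGrid:
    outdir = Path(outdir)
    reps = sorted(outdir.glob("viability_rep*.csv"))
    if not reps:
        raise FileNotFoundError(f"no viability_rep*.csv under {outdir}")
    mats, doses_a, doses_b = [], None, None
    for path in reps:
        df = pd.read_csv(path, index_col=0)
        doses_a = df.index.to_numpy(dtype=float)
        doses_b = df.columns.to_numpy(dtype=float)
        mats.append(df.to_numpy(dtype=float))
    return DoseGrid(
        doses_a=doses_a, doses_b=doses_b, viability=np.stack(mats), drug_a=drug_a, drug_b=drug_b
    )
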