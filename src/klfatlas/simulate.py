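"""Synthetic snRNA-seq data generator with known ground truth.

Emulates the structure of a two-breed bovine longissimus dorsi single-nucleus
experiment: 6 biological replicates per breed, 11 muscle-microenvironment
cell types spread over 16 clusters, per-type marker genes, a 14-gene focal
KLF panel with breed- and cell-type-specific log2 fold effects, mitochondrial
genes, negative-binomial (gamma-Poisson) counts, log-normal library sizes,
and Dirichlet-distributed replicate-level cell-type proportions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import sparse

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_reference_markers",
    "default_panel_effects",
    "DEFAULT_CELL_TYPES",
    "DEFAULT_PANEL_GENES",
]

# 14 bovine KLF family members (KLF14/16/17/18 have no bovine ortholog).
DEFAULT_PANEL_GENES = tuple(f"KLF{i}" for i in list(range(1, 14)) + [15])

DEFAULT_CELL_TYPES = (
    "Myofiber",
    "FAP",
    "FAP-1",
    "Satellite cell",
    "Adipocyte",
    "VEndoC",
    "LEndoC",
    "Pericyte",
    "Macrophage",
    "T cell",
    "B cell",
)

# 16 clusters over the 11 types: abundant heterogeneous types split into
# several clusters, rare types keep one.
DEFAULT_CLUSTERS_PER_TYPE = {
    "Myofiber": 3,
    "FAP": 2,
    "FAP-1": 2,
    "Satellite cell": 1,
    "Adipocyte": 1,
    "VEndoC": 2,
    "LEndoC": 1,
    "Pericyte": 1,
    "Macrophage": 1,
    "T cell": 1,
    "B cell": 1,
}

# Mean cell-type proportions per breed. The meat breed (ANG) carries more
# myofiber nuclei; the dairy breed (HST) more stromal populations (FAPs,
# pericytes, adipocytes) — the compositional contrast the study reports.
DEFAULT_BREED_PROPORTIONS = {
    "ANG": {
        "Myofiber": 0.30, "FAP": 0.15, "FAP-1": 0.10, "Satellite cell": 0.08,
        "Adipocyte": 0.05, "VEndoC": 0.08, "LEndoC": 0.06, "Pericyte": 0.04,
        "Macrophage": 0.07, "T cell": 0.04, "B cell": 0.03,
    },
    "HST": {
        "Myofiber": 0.18, "FAP": 0.18, "FAP-1": 0.15, "Satellite cell": 0.07,
        "Adipocyte": 0.055, "VEndoC": 0.09, "LEndoC": 0.07, "Pericyte": 0.048,
        "Macrophage": 0.08, "T cell": 0.045, "B cell": 0.032,
    },
}

# Dirichlet concentration: small on purpose — per-replicate compositions are
# highly variable between animals (the study's myofiber SD exceeds its mean).
DEFAULT_PROPORTION_CONCENTRATION = 3.0


def default_panel_effects(
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
    panel_genes: tuple[str, ...] = DEFAULT_PANEL_GENES,
    breeds: tuple[str, ...] = ("ANG", "HST"),
) -> np.ndarray:
    """Breed x cell-type x panel-gene log2-fold effects.

    Defaults encode the qualitative patterns of the focal panel: KLF9, KLF10
    (HST-enriched) and KLF12 (ANG-enriched) carry the largest global breed
    effects, with |effect(KLF9)| largest; KLF6 is elevated in lymphatic
    endothelium in both breeds and carries an additional ANG-specific boost
    restricted to that type; the whole panel is mildly elevated in vascular
    endothelium (driving the module-score ordering).
    """
    eff = np.zeros((len(breeds), len(cell_types), len(panel_genes)))
    gi = {g: j for j, g in enumerate(panel_genes)}
    ti = {t: i for i, t in enumerate(cell_types)}
    b = {name: k for k, name in enumerate(breeds)}

    def add(breed, cell_type, gene, value):
        if gene in gi and cell_type is None:
            eff[b[breed], :, gi[gene]] += value
        elif gene in gi and cell_type in ti:
            eff[b[breed], ti[cell_type], gi[gene]] += value

    for breed in breeds:
        # baseline cell-type elevations shared by both breeds
        add(breed, "LEndoC", "KLF6", 1.5)
        if "VEndoC" in ti:
            for g in panel_genes:
                eff[b[breed], ti["VEndoC"], gi[g]] += 0.8
    # global breed differentials (positive = HST-enriched)
    add("HST", None, "KLF9", 1.0)
    add("HST", None, "KLF10", 0.75)
    add("ANG", None, "KLF12", 0.6)
    # cell-type-restricted breed differential: KLF6 in LEndoC only
    add("ANG", "LEndoC", "KLF6", 1.2)
    return eff


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Counts are gamma-Poisson: for cell c and gene g,
    ``count ~ Poisson(Gamma(1/disp, disp * mu))`` with
    ``mu = libsize_c * p_{g|type,breed}`` so that
    ``Var = mu + nb_dispersion * mu**2``.
    """

    breed_labels: tuple[str, str] = ("ANG", "HST")
    replicates_per_breed: int = 6
    cells_per_replicate: int = 500
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    clusters_per_type: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTERS_PER_TYPE))
    proportion_alpha: dict[str, dict[str, float]] | None = None
    n_genes: int = 2000
    markers_per_type: int = 20
    marker_log2fc: float = 2.0
    panel_genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    panel_effects: np.ndarray | None = None
    mito_genes: int = 10
    mito_rate: float = 0.03
    bad_cell_fraction: float = 0.05
    bad_cell_mito_rate: float = 0.15
    nb_dispersion: float = 0.3
    libsize_logmean: float = float(np.log(1500.0))
    libsize_logsd: float = 0.3
    panel_base_expr: float | None = 1.5
    seed: int = 0

    @property
    def n_breeds(self) -> int:
        return len(self.breed_labels)

    @property
    def n_clusters(self) -> int:
        return sum(self.clusters_per_type.get(t, 1) for t in self.cell_types)

    def resolved_alpha(self) -> np.ndarray:
        """Dirichlet alpha, shape (n_breeds, n_types)."""
        if self.proportion_alpha is not None:
            out = np.array([
                [float(self.proportion_alpha[b][t]) for t in self.cell_types]
                for b in self.breed_labels
            ])
        else:
            out = np.empty((self.n_breeds, len(self.cell_types)))
            for k, breed in enumerate(self.breed_labels):
                props = DEFAULT_BREED_PROPORTIONS.get(breed)
                if props is None or any(t not in props for t in self.cell_types):
                    p = np.full(len(self.cell_types), 1.0 / len(self.cell_types))
                else:
                    p = np.array([props[t] for t in self.cell_types])
                    p = p / p.sum()
                out[k] = DEFAULT_PROPORTION_CONCENTRATION * p
        if np.any(out <= 0):
            raise ValueError("Dirichlet alpha must be positive")
        return out

    def resolved_panel_effects(self) -> np.ndarray:
        if self.panel_effects is None:
            return default_panel_effects(
                tuple(self.cell_types), tuple(self.panel_genes),
                tuple(self.breed_labels))
        eff = np.asarray(self.panel_effects, dtype=float)
        expected = (self.n_breeds, len(self.cell_types), len(self.panel_genes))
        if eff.shape != expected:
            raise ValueError(
                f"panel_effects shape {eff.shape} != expected {expected}")
        return eff

    def validate(self) -> None:
        if not self.cell_types:
            raise ValueError("cell_types must be nonempty")
        if self.n_breeds != 2:
            raise ValueError("exactly two breeds are supported")
        for name, val in [
            ("replicates_per_breed", self.replicates_per_breed),
            ("cells_per_replicate", self.cells_per_replicate),
            ("n_genes", self.n_genes),
            ("markers_per_type", self.markers_per_type),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.mito_rate < 1:
            raise ValueError("mito_rate must be in [0, 1)")
        n_structured = (len(self.panel_genes) + self.mito_genes
                        + self.markers_per_type * len(self.cell_types))
        if self.n_genes < n_structured:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_structured} "
                "panel+marker+mito genes")
        self.resolved_alpha()
        self.resolved_panel_effects()

    # -- YAML round-trip (CLI config files) --------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("breed_labels", "cell_types", "panel_genes"):
            d[key] = list(d[key])
        if d["panel_effects"] is not None:
            d["panel_effects"] = np.asarray(d["panel_effects"]).tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for key in ("breed_labels", "cell_types", "panel_genes"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("panel_effects") is not None:
            kwargs["panel_effects"] = np.asarray(kwargs["panel_effects"], float)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    marker_assignment: dict[str, list[str]]      # cell type -> marker genes
    cluster_types: dict[str, str]                # cluster label -> cell type
    proportions: pd.DataFrame                    # replicate x type, rows sum to 1
    panel_effects: pd.DataFrame                  # (breed, type) x panel gene log2FC
    expected_means: pd.DataFrame | None = None   # (breed, type) x gene NB mean at libsize=1


def _gene_layout(config: SimConfig):
    """Deterministic gene naming shared by the generator and the reference
    marker writer: panel genes, then per-type markers, mito genes, filler."""
    names: list[str] = list(config.panel_genes)
    marker_assignment: dict[str, list[str]] = {}
    for ti, ctype in enumerate(config.cell_types):
        genes = [f"MK{ti:02d}-{j:02d}" for j in range(config.markers_per_type)]
        marker_assignment[ctype] = genes
        names.extend(genes)
    mito = [f"MT-{j + 1}" for j in range(config.mito_genes)]
    names.extend(mito)
    n_filler = config.n_genes - len(names)
    names.extend(f"G{j:05d}" for j in range(n_filler))
    if len(set(names)) != len(names):
        raise ValueError("gene name collision; rename panel genes")
    return names, marker_assignment, mito


def generate_dataset(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw one synthetic dataset.

    Returns an AnnData with raw integer counts (cells x genes, CSR) and
    per-cell metadata (breed, replicate, cluster, true_type), plus the
    ground truth. Identical config (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names, marker_assignment, mito_names = _gene_layout(config)
    n_genes = config.n_genes
    gene_index = {g: i for i, g in enumerate(names)}
    mito_mask = np.zeros(n_genes, dtype=bool)
    mito_mask[[gene_index[g] for g in mito_names]] = True
    panel_idx = np.array([gene_index[g] for g in config.panel_genes], int)

    # gene-level baseline relative expression; panel genes share a fixed
    # baseline so their planted log2 effects are directly comparable
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    if config.panel_base_expr is not None:
        base[panel_idx] = config.panel_base_expr

    alpha = config.resolved_alpha()
    effects = config.resolved_panel_effects()
    types = list(config.cell_types)
    n_types = len(types)

    # per-(breed, type) expression profiles, mito share handled per cell
    profiles = np.tile(base, (config.n_breeds, n_types, 1))
    for ti, ctype in enumerate(types):
        midx = [gene_index[g] for g in marker_assignment[ctype]]
        profiles[:, ti, midx] *= 2.0 ** config.marker_log2fc
    profiles[:, :, panel_idx] *= 2.0 ** effects

    nonmito = profiles[:, :, ~mito_mask]
    nonmito_frac = nonmito / nonmito.sum(axis=2, keepdims=True)
    mito_base = base[mito_mask]
    mito_frac = (mito_base / mito_base.sum()) if config.mito_genes else None

    # replicate-level compositions
    rep_rows = []
    prop_rows = []
    for bi, breed in enumerate(config.breed_labels):
        for r in range(config.replicates_per_breed):
            rep = f"{breed}_{r + 1}"
            props = rng.dirichlet(alpha[bi])
            rep_rows.append((bi, breed, rep, props))
            prop_rows.append(pd.Series(props, index=types, name=rep))
    proportions = pd.DataFrame(prop_rows)

    # cluster labels per type
    cluster_names: dict[str, list[str]] = {}
    cluster_types: dict[str, str] = {}
    cid = 0
    for ctype in types:
        k = config.clusters_per_type.get(ctype, 1)
        labels = [f"C{cid + j}" for j in range(k)]
        cluster_names[ctype] = labels
        for lab in labels:
            cluster_types[lab] = ctype
        cid += k

    obs_rows = []
    count_blocks = []
    disp = config.nb_dispersion
    for bi, breed, rep, props in rep_rows:
        n_cells = config.cells_per_replicate
        type_draw = rng.choice(n_types, size=n_cells, p=props)
        libsize = rng.lognormal(config.libsize_logmean, config.libsize_logsd,
                                size=n_cells)
        bad = rng.random(n_cells) < config.bad_cell_fraction
        mito_rate = np.where(bad, config.bad_cell_mito_rate, config.mito_rate)
        counts = np.zeros((n_cells, n_genes), dtype=np.int32)
        for ti in range(n_types):
            sel = type_draw == ti
            if not sel.any():
                continue
            r = mito_rate[sel][:, None]
            mu = np.empty((int(sel.sum()), n_genes))
            mu[:, ~mito_mask] = (1.0 - r) * nonmito_frac[bi, ti]
            if config.mito_genes:
                mu[:, mito_mask] = r * mito_frac
            mu *= libsize[sel][:, None]
            if disp > 0:
                lam = rng.gamma(shape=1.0 / disp, scale=disp * mu)
            else:
                lam = mu
            counts[sel] = rng.poisson(lam)
        count_blocks.append(sparse.csr_matrix(counts))
        cluster_draw = rng.integers(0, 1 << 30, size=n_cells)
        for i in range(n_cells):
            ctype = types[type_draw[i]]
            clusters = cluster_names[ctype]
            cluster = clusters[cluster_draw[i] % len(clusters)]
            obs_rows.append((f"{rep}-{i:05d}", breed, rep, cluster, ctype))

    X = sparse.vstack(count_blocks, format="csr").astype(np.int64)
    obs = pd.DataFrame(
        obs_rows, columns=["barcode", "breed", "replicate", "cluster",
                           "true_type"]).set_index("barcode")
    var = pd.DataFrame(index=pd.Index(names, name="gene"))
    var["mito"] = mito_mask
    marker_of = np.array([""] * n_genes, dtype=object)
    for ctype, genes in marker_assignment.items():
        for g in genes:
            marker_of[gene_index[g]] = ctype
    var["marker_type"] = marker_of
    var["panel"] = False
    var.iloc[panel_idx, var.columns.get_loc("panel")] = True

    adata = ad.AnnData(X=X, obs=obs, var=var)

    eff_index = pd.MultiIndex.from_product(
        [config.breed_labels, types], names=["breed", "cell_type"])
    panel_df = pd.DataFrame(
        effects.reshape(-1, len(config.panel_genes)), index=eff_index,
        columns=list(config.panel_genes))
    mean_profiles = np.empty((config.n_breeds, n_types, n_genes))
    for bi in range(config.n_breeds):
        for ti in range(n_types):
            mp = np.zeros(n_genes)
            mp[~mito_mask] = (1 - config.mito_rate) * nonmito_frac[bi, ti]
            if config.mito_genes:
                mp[mito_mask] = config.mito_rate * mito_frac
            mean_profiles[bi, ti] = mp
    expected_means = pd.DataFrame(
        mean_profiles.reshape(-1, n_genes), index=eff_index, columns=names)

    truth = GroundTruth(
        marker_assignment=marker_assignment,
        cluster_types=cluster_types,
        proportions=proportions,
        panel_effects=panel_df,
        expected_means=expected_means,
    )
    return adata, truth


def generate_reference_markers(
    config: SimConfig,
    decoy_fraction: float = 0.0,
    seed: int | None = None,
) -> dict[str, set[str]]:
    """Reference marker table (cell type -> gene set), a stand-in for a
    literature-curated marker list.

    ``decoy_fraction`` of each type's genes are replaced by non-marker
    filler genes, to probe annotation robustness against a noisy reference.
    """
    if not config.cell_types:
        raise ValueError("cell_types must be nonempty")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must be in [0, 1]")
    names, marker_assignment, mito_names = _gene_layout(config)
    structured = set(mito_names) | set(config.panel_genes)
    for genes in marker_assignment.values():
        structured.update(genes)
    filler = [g for g in names if g not in structured]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ref: dict[str, set[str]] = {}
    for ctype in config.cell_types:
        genes = list(marker_assignment[ctype])
        n_decoy = int(round(decoy_fraction * len(genes)))
        if n_decoy:
            if n_decoy > len(filler):
                raise ValueError("not enough non-marker genes for decoys")
            drop = rng.choice(len(genes), size=n_decoy, replace=False)
            decoys = rng.choice(filler, size=n_decoy, replace=False)
            for slot, decoy in zip(sorted(drop), decoys):
                genes[slot] = str(decoy)
        ref[ctype] = set(genes)
    return ref
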