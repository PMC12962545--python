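"""Data model, readers/writers and validation for the pipeline inputs.

Five plain-text inputs describe one study: an ASV count table with an
ASV -> fungal-species taxonomy, per-sample metadata (host species, life
history, phylogenetic group, greenhouse block, year, replicate), a host
plant phylogeny in Newick, the factorial feedback-experiment biomass
table, and a growth-assay summary table for the meta-analysis. All tables
are TSV with a header row; lines starting with '#' are comments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import phylo

logger = logging.getLogger("mycofeedback")

LIFE_HISTORIES = ("early", "late")
PHYLO_GROUPS = ("lilies", "grasses", "legumes", "milkweeds", "mints", "asters")

METADATA_COLUMNS = [
    "sample_id", "host_species", "life_history", "phylo_group",
    "block", "year", "replicate",
]
FEEDBACK_COLUMNS = ["host_species", "training_species", "block", "replicate", "biomass"]
ASSAY_COLUMNS = [
    "study_id", "host_species", "life_history", "phylo_group", "fungal_isolate",
    "mean_inoc", "sd_inoc", "n_inoc", "mean_ctrl", "sd_ctrl", "n_ctrl",
]


def read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - message wrapper
        raise ValueError(f"malformed table {path}: {exc}") from exc


@dataclass
class AsvCountTable:
    """Samples x ASVs integer read counts with an ASV -> species map."""

    counts: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self):
        x = self.counts.to_numpy()
        if (x < 0).any():
            raise ValueError("negative read counts")
        if not np.allclose(x, np.round(x)):
            raise ValueError("non-integral read counts")
        self.counts = self.counts.astype(np.int64)
        missing = [a for a in self.counts.columns if a not in self.taxonomy.index]
        if missing:
            raise ValueError(f"taxonomy missing ASVs: {missing}")
        if self.taxonomy.index.duplicated().any():
            raise ValueError("duplicate ASV ids in taxonomy")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class SampleMetadata:
    """Per-sample design metadata, indexed by sample_id."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in METADATA_COLUMNS if c not in t.columns
                   and c != "sample_id"]
        if t.index.name != "sample_id":
            if "sample_id" not in t.columns:
                raise ValueError("metadata needs a sample_id column")
            t = t.set_index("sample_id")
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        t = t.copy()
        t["host_species"] = t["host_species"].map(phylo.canonical_label)
        bad_lh = set(t["life_history"]) - set(LIFE_HISTORIES)
        if bad_lh:
            raise ValueError(f"unknown life_history values: {sorted(bad_lh)}")
        bad_pg = set(t["phylo_group"]) - set(PHYLO_GROUPS)
        if bad_pg:
            raise ValueError(f"unknown phylo_group values: {sorted(bad_pg)}")
        t["year"] = t["year"].astype(int)
        self.table = t


@dataclass
class HostPhylogeny:
    """Rooted host tree with branch lengths."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, source: str) -> "HostPhylogeny":
        return cls(phylo.read_newick(source))

    @property
    def tip_labels(self) -> list[str]:
        return phylo.tip_labels(self.tree)

    def patristic_distances(self) -> pd.DataFrame:
        return phylo.patristic_distances(self.tree)

    def covariance(self, scale: str = "mean_diag") -> pd.DataFrame:
        return phylo.phylo_covariance(self.tree, scale=scale)

    def to_newick(self) -> str:
        return phylo.tree_to_newick(self.tree)


@dataclass
class FeedbackDesign:
    """Replicate biomass of hosts grown in conspecific/heterospecific soils."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in FEEDBACK_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"feedback table missing columns: {missing}")
        t = t.copy()
        for c in ("host_species", "training_species"):
            t[c] = t[c].map(phylo.canonical_label)
        if (t["biomass"] <= 0).any():
            raise ValueError("biomass must be > 0")
        self.table = t

    def pairs(self) -> list[tuple[str, str]]:
        """Unordered species pairs with all four cells present."""
        cells = set(zip(self.table["host_species"], self.table["training_species"]))
        species = sorted({s for c in cells for s in c})
        out = []
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                need = {(a, a), (a, b), (b, a), (b, b)}
                if need <= cells:
                    out.append((a, b))
        return out


@dataclass
class GrowthAssayTable:
    """Summary statistics of inoculated vs. control growth assays."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in ASSAY_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"assay table missing columns: {missing}")
        if (t[["mean_inoc", "mean_ctrl"]] <= 0).any().any():
            raise ValueError("assay means must be > 0")
        if (t[["sd_inoc", "sd_ctrl"]] < 0).any().any():
            raise ValueError("assay SDs must be >= 0")
        if (t[["n_inoc", "n_ctrl"]] < 2).any().any():
            raise ValueError("assay n must be >= 2")
        self.table = t.copy()


@dataclass
class PipelineConfig:
    """Paths and numeric settings shared by all pipeline stages."""

    counts: str = "counts.tsv"
    taxonomy: str = "taxonomy.tsv"
    metadata: str = "metadata.tsv"
    tree: str = "tree.nwk"
    feedback: str = "feedback.tsv"
    assays: str = "assays.tsv"
    data_dir: str = "."
    pseudocount: float = 1.0
    rarefaction_depth: int = 100
    rarefaction_draws: int = 100
    n_permutations: int = 999
    seed: int = 0
    years: tuple = (1, 2)
    dissimilarity_year: int = 2
    logit_eps_rule: str = "half_depth"  # epsilon = 1/(2*depth)

    def __post_init__(self):
        if self.n_permutations < 99:
            raise ValueError("permutation count must be >= 99")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")
        self.years = tuple(int(y) for y in self.years)

    def path(self, name: str) -> Path:
        return Path(self.data_dir) / getattr(self, name)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            repr(sorted(dataclasses.asdict(self).items())).encode()
        ).hexdigest()[:12]


@dataclass
class Dataset:
    counts: AsvCountTable
    metadata: SampleMetadata
    tree: HostPhylogeny
    feedback: FeedbackDesign
    assays: GrowthAssayTable


def load_dataset(config: PipelineConfig) -> Dataset:
    """Load and cross-validate the five pipeline inputs."""
    counts = read_tsv(config.path("counts")).set_index("sample_id")
    tax = read_tsv(config.path("taxonomy")).set_index("asv_id")["species"]
    table = AsvCountTable(counts=counts, taxonomy=tax)
    metadata = SampleMetadata(read_tsv(config.path("metadata")))
    tree = HostPhylogeny.from_newick(str(config.path("tree")))
    feedback = FeedbackDesign(read_tsv(config.path("feedback")))
    assays = GrowthAssayTable(read_tsv(config.path("assays")))

    extra = set(metadata.table.index) ^ set(table.sample_ids)
    if extra:
        raise ValueError(f"metadata/count sample mismatch: {sorted(extra)[:5]}")
    logger.info(
        "loaded %d samples, %d ASVs, %d host species",
        len(table.sample_ids), len(table.asv_ids),
        metadata.table["host_species"].nunique(),
    )
    return Dataset(table, metadata, tree, feedback, assays)


@dataclass
class ValidationReport:
    hosts_missing_from_tree: list = field(default_factory=list)
    nonestimable_pairs: list = field(default_factory=list)
    low_n_assays: list = field(default_factory=list)
    zero_asvs: list = field(default_factory=list)
    zero_depth_samples: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not any(dataclasses.asdict(self).values())


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Cross-reference the loaded tables; report-only (stages refuse
    flagged inputs)."""
    rep = ValidationReport()
    tips = set(dataset.tree.tip_labels)
    hosts = set(dataset.metadata.table["host_species"])
    hosts |= set(dataset.feedback.table["host_species"])
    hosts |= set(dataset.feedback.table["training_species"])
    rep.hosts_missing_from_tree = sorted(hosts - tips)

    cells = set(zip(dataset.feedback.table["host_species"],
                    dataset.feedback.table["training_species"]))
    species = sorted({s for c in cells for s in c})
    # any pair of co-conditioned species missing one of the four factorial
    # cells cannot enter the interaction coefficient
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            have = {(a, a), (a, b), (b, a), (b, b)} & cells
            if 0 < len({(a, b), (b, a)} & cells) and len(have) < 4:
                rep.nonestimable_pairs.append((a, b))

    t = dataset.assays.table
    low = t[(t["n_inoc"] < 2) | (t["n_ctrl"] < 2)]
    rep.low_n_assays = low.index.tolist()

    zero_cols = dataset.counts.counts.columns[
        dataset.counts.counts.sum(axis=0) == 0
    ]
    rep.zero_asvs = list(zero_cols)
    rep.zero_depth_samples = list(
        dataset.counts.counts.index[dataset.counts.depths() < 1]
    )
    return rep


def write_results(
    tables: dict,
    out_dir,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write result tables as TSV with a reproducibility comment header."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = [
        f"# mycofeedback {__version__}",
        f"# config_hash: {config.digest() if config else 'none'}",
        f"# seed: {seed if seed is not None else (config.seed if config else 'none')}",
    ]
    paths = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g",
                      lineterminator="\n")
        paths.append(path)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("\n".join(header) + "\nfile\n")
        for p in paths:
            fh.write(p.name + "\n")
    return paths
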