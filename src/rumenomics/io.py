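"""Readers and writers for the plain-text exchange formats, plus the
pipeline configuration object.

All tables are TSV/CSV so every artifact is inspectable; networks are also
exported as GraphML.  Readers validate structure and report offending
row/column coordinates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .abundance import OtuTable
from .coexpression import CoexpressionNetwork
from .diversity import DistanceMatrix
from .errors import ValidationError
from .expression import ExpressionMatrix
from .integration import SCFAS, ScfaProfile
from .synthetic import SyntheticConfig


# ---------------------------------------------------------------- OTU side

def write_otu_counts(t: OtuTable, path) -> None:
    t.counts.T.rename_axis("otu_id").to_csv(path, sep="\t")


def read_otu_counts(path) -> pd.DataFrame:
    """Counts TSV (first column OTU id, remaining columns samples) to a
    samples x OTUs frame; non-integer or negative entries are rejected with
    their coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    values = raw.to_numpy()
    numeric = pd.to_numeric(raw.stack(), errors="coerce")
    if numeric.isna().any():
        otu, sample = numeric.index[numeric.isna().argmax()]
        raise ValidationError(f"non-numeric count at OTU {otu!r}, sample {sample!r}")
    values = numeric.unstack().reindex(index=raw.index, columns=raw.columns).to_numpy(float)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(f"negative count at OTU {raw.index[i]!r}, sample {raw.columns[j]!r}")
    if not np.allclose(values, np.round(values)):
        i, j = np.argwhere(values != np.round(values))[0]
        raise ValidationError(
            f"non-integer count at OTU {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    out = pd.DataFrame(values.astype(np.int64), index=raw.index, columns=raw.columns).T
    return out.rename_axis(index=None, columns=None)


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.rename_axis("otu_id").to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).rename_axis(index=None)


def write_metadata(groups: pd.Series, path, animals: pd.Series | None = None) -> None:
    out = pd.DataFrame({"group": groups})
    if animals is not None:
        out["animal"] = animals
    out.rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0).rename_axis(index=None)
    if "group" not in meta.columns:
        raise ValidationError(f"metadata file {path} lacks a 'group' column")
    return meta


def read_otu_table(counts_path, taxonomy_path, metadata_path) -> OtuTable:
    counts = read_otu_counts(counts_path)
    taxonomy = read_taxonomy(taxonomy_path)
    meta = read_metadata(metadata_path)
    missing = set(counts.index) - set(meta.index)
    if missing:
        raise ValidationError(f"samples missing from metadata: {sorted(missing)}")
    animals = meta["animal"] if "animal" in meta.columns else None
    return OtuTable(
        counts=counts,
        taxonomy=taxonomy,
        groups=meta["group"].reindex(counts.index),
        animals=animals.reindex(counts.index) if animals is not None else None,
    )


# --------------------------------------------------------- expression side

def write_expression(e: ExpressionMatrix, path, families_path=None) -> None:
    e.rpkm.rename_axis("gene_id").to_csv(path, sep="\t")
    if families_path is not None:
        e.families.rename("family").to_frame().rename_axis("gene_id").to_csv(
            families_path, sep="\t")


def read_expression(path, families_path, metadata_path) -> ExpressionMatrix:
    rpkm = pd.read_csv(path, sep="\t", index_col=0).rename_axis(index=None)
    if (rpkm.to_numpy() < 0).any():
        i, j = np.argwhere(rpkm.to_numpy() < 0)[0]
        raise ValidationError(
            f"negative RPKM at gene {rpkm.index[i]!r}, sample {rpkm.columns[j]!r}"
        )
    fam = pd.read_csv(families_path, sep="\t", index_col=0)["family"]
    meta = read_metadata(metadata_path)
    missing = set(rpkm.columns) - set(meta.index)
    if missing:
        raise ValidationError(f"samples missing from metadata: {sorted(missing)}")
    return ExpressionMatrix(
        rpkm=rpkm, families=fam.reindex(rpkm.index).fillna("other"),
        groups=meta["group"],
    )


def read_pathway_map(path) -> dict:
    """Gene-to-tag map from a two-column TSV; malformed lines are reported
    with their line number.  Duplicate tags per gene are de-duplicated.
    """
    mapping: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValidationError(f"malformed pathway map at {path}:{lineno}: {line!r}")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return {gene: sorted(tags) for gene, tags in mapping.items()}


# --------------------------------------------------------------- SCFA side

def write_scfa(s: ScfaProfile, path) -> None:
    cols = ["sample", "time_h", *SCFAS, "pH", "total"]
    s.data[[c for c in cols if c in s.data.columns]].to_csv(path, index=False)


def read_scfa(path, metadata_path) -> ScfaProfile:
    data = pd.read_csv(path)
    meta = read_metadata(metadata_path)
    missing = set(data["sample"]) - set(meta.index)
    if missing:
        raise ValidationError(f"samples missing from metadata: {sorted(missing)}")
    return ScfaProfile(data=data, groups=meta["group"])


# ----------------------------------------------------------- other formats

def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.to_frame().to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(ids=tuple(frame.index), values=frame.to_numpy(float))


def write_network(net: CoexpressionNetwork, edges_path, graphml_path=None) -> None:
    net.edges_frame().to_csv(edges_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)


def read_network_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ------------------------------------------------------------ configuration

@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration: either input paths or a synthetic
    study, plus every stage threshold and flag.
    """

    out_dir: str = "results"
    seed: int = 0
    # inputs: either simulate or read from files
    simulate: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    otu_counts: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    expression: str | None = None
    gene_families: str | None = None
    scfa: str | None = None
    pathway_map: str | None = None
    # thresholds (community)
    min_count: int = 3
    detectable_threshold: float = 0.01
    # thresholds (expression / network)
    min_rpkm: float = 1.0
    de_alpha: float = 0.05
    de_adjust: str = "none"
    coexpr_rho_min: float = 0.85
    coexpr_p_max: float = 0.01
    coexpr_absolute: bool = False
    # thresholds (integration)
    screen_rho_min: float = 0.6
    screen_p_max: float = 0.05
    screen_absolute: bool = False
    proportion_time: int = 8
    cca_standardize: bool = True
    # ordination
    nmds_k: int = 2
    nmds_starts: int = 8
    anosim_permutations: int = 999

    def validate(self) -> None:
        if self.simulate is None:
            needed = ("otu_counts", "taxonomy", "metadata", "expression",
                      "gene_families", "scfa")
            missing = [k for k in needed if getattr(self, k) is None]
            if missing:
                raise ValidationError(f"no synthetic config and missing inputs: {missing}")
        for name in ("detectable_threshold", "de_alpha", "coexpr_p_max", "screen_p_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("coexpr_rho_min", "screen_rho_min"):
            v = getattr(self, name)
            if not -1 <= v <= 1:
                raise ValidationError(f"{name} must be in [-1, 1], got {v}")
        if self.min_count < 0 or self.min_rpkm < 0 or self.anosim_permutations < 1:
            raise ValidationError("invalid threshold configuration")
        if self.simulate is not None:
            self.simulate.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
            d["simulate"]["group_names"] = list(self.simulate.group_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulate")
        if sim is not None:
            if "group_names" in sim:
                sim = {**sim, "group_names": tuple(sim["group_names"])}
            d["simulate"] = SyntheticConfig(**sim)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def read_inputs(cfg: PipelineConfig) -> tuple[OtuTable, ExpressionMatrix, ScfaProfile]:
    """Load and cross-validate the three input tables from disk.

    Sample ids must be consistent across the OTU, expression, and SCFA
    tables; offenders are listed in the error.
    """
    t = read_otu_table(cfg.otu_counts, cfg.taxonomy, cfg.metadata)
    e = read_expression(cfg.expression, cfg.gene_families, cfg.metadata)
    s = read_scfa(cfg.scfa, cfg.metadata)
    ids = set(t.sample_ids)
    for name, other in (("expression", set(e.sample_ids)), ("scfa", set(s.sample_ids))):
        if other != ids:
            raise ValidationError(
                f"sample-id mismatch between OTU table and {name}: "
                f"missing {sorted(ids - other)}, extra {sorted(other - ids)}"
            )
    return t, e, s
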