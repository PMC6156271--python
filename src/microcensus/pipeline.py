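"""End-to-end pipeline: search -> QC -> binning -> aggregation -> census -> ranks.

Each stage is a function over files, so running stages one at a time (as the
CLI subcommands do) produces bit-for-bit the same artifacts as
:func:`run_pipeline`. Every run writes a manifest recording the config hash,
seed and output checksums; reruns with an identical config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .aggregate import count_fractions, depth_weighted_fractions
from .census import CopyNumberModel, census_from_profiles, load_cell_totals
from .classify import CutoffLadder, assign_bin_series, assign_level
from .errors import DataError, MicrocensusError
from .qc import QCThresholds, RETAINED, run_qc
from .rank import genus_abundances, genus_label_from_taxonomy, top_n
from .search import AlignmentParams, HITS_COLUMNS, search_all
from .util import sha256_file, sha256_text

logger = logging.getLogger(__name__)

OUTPUT_FILES = ("hits.tsv", "hits_env.tsv", "qc_report.tsv", "qc_summary.json",
                "classifications.tsv", "profiles.tsv", "census.tsv",
                "census_headline.json", "rank_abundance.tsv")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    queries_fasta: str
    metadata_tsv: str
    cultured_fasta: str
    output_dir: str
    cultured_taxonomy_tsv: str | None = None
    environmental_fasta: str | None = None
    cell_totals_tsv: str | None = None
    seed: int = 0
    cutoffs: CutoffLadder = field(default_factory=CutoffLadder)
    qc: QCThresholds = field(default_factory=QCThresholds)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    copy_model: CopyNumberModel = field(default_factory=CopyNumberModel)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        for key, typ in (("cutoffs", CutoffLadder), ("qc", QCThresholds),
                         ("alignment", AlignmentParams),
                         ("copy_model", CopyNumberModel)):
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_search(queries_fasta, refs_fasta, out_tsv,
                 params: AlignmentParams | None = None) -> pd.DataFrame:
    """Top-hit search of every query against the cultured database."""
    queries = io.read_fasta(queries_fasta)
    refs = io.read_fasta(refs_fasta)
    hits = search_all(queries, refs, params)
    io.write_tsv(hits, out_tsv)
    return hits


def stage_search_env(queries_fasta, env_fasta, hits_tsv, out_tsv,
                     params: AlignmentParams | None = None,
                     coverage_threshold: float = 0.90) -> pd.DataFrame:
    """Search the environmental database for chimera-screen candidates.

    Only queries whose cultured-hit alignment spans less than
    ``coverage_threshold`` of their length (or that had no cultured hit)
    are aligned; everything else is outside the screen.
    """
    queries = io.read_fasta(queries_fasta)
    hits = io.read_tsv(hits_tsv).set_index("query_id")
    screened = {}
    for qid, seq in queries.items():
        if qid not in hits.index:
            continue
        row = hits.loc[qid]
        if bool(row["no_hit"]) or float(row["qlen_aligned"]) / len(seq) < coverage_threshold:
            screened[qid] = seq
    if screened:
        env_refs = io.read_fasta(env_fasta)
        env_hits = search_all(screened, env_refs, params)
    else:
        env_hits = pd.DataFrame(columns=HITS_COLUMNS)
    io.write_tsv(env_hits, out_tsv)
    return env_hits


def _records_table(queries: dict[str, str], metadata: pd.DataFrame) -> pd.DataFrame:
    meta = metadata.set_index("query_id")
    missing = [q for q in queries if q not in meta.index]
    if missing:
        raise DataError(f"metadata missing for query {missing[0]!r}")
    records = meta.loc[list(queries)].copy()
    records["length"] = [len(queries[q]) for q in records.index]
    return records


def stage_qc(queries_fasta, metadata_tsv, hits_tsv, hits_env_tsv,
             out_report, out_summary,
             thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Apply the retention rules; write the per-query report and summary."""
    queries = io.read_fasta(queries_fasta)
    metadata = io.read_metadata(metadata_tsv)
    records = _records_table(queries, metadata)
    hits = io.read_tsv(hits_tsv)
    hits_env = io.read_tsv(hits_env_tsv) if hits_env_tsv and Path(hits_env_tsv).exists() else None
    report = run_qc(records, hits, hits_env, thresholds)
    io.write_tsv(report.table.reset_index(), out_report)
    Path(out_summary).write_text(json.dumps(report.summary(), indent=2, sort_keys=True))
    return report.table


def stage_classify(hits_tsv, qc_report_tsv, out_tsv,
                   cutoffs: CutoffLadder | None = None) -> pd.DataFrame:
    """Assign novelty bins (and levels) to retained queries."""
    cutoffs = cutoffs or CutoffLadder()
    hits = io.read_tsv(hits_tsv)
    qc_table = io.read_tsv(qc_report_tsv)
    retained = set(qc_table.loc[qc_table["outcome"] == RETAINED, "query_id"])
    sel = hits[hits["query_id"].isin(retained)].copy()
    sel["bin"] = assign_bin_series(sel["pident"], cutoffs).to_numpy()
    sel["level"] = [assign_level(p, cutoffs) for p in sel["pident"]]
    out = sel[["query_id", "pident", "bin", "level"]].reset_index(drop=True)
    io.write_tsv(out, out_tsv)
    return out


def build_observations(classifications: pd.DataFrame,
                       metadata: pd.DataFrame) -> pd.DataFrame:
    """Join classifications with metadata into the observation table."""
    obs = classifications.merge(metadata, on="query_id", how="left", validate="1:1")
    if obs["environment"].isna().any():
        raise DataError("metadata missing environment for some classified queries")
    if "read_depth" not in obs.columns:
        obs["read_depth"] = float("nan")
    if "taxonomy" not in obs.columns:
        obs["taxonomy"] = ""
    obs["genus_label"] = obs["taxonomy"].map(genus_label_from_taxonomy)
    return obs


def stage_aggregate(classifications_tsv, metadata_tsv, out_tsv) -> pd.DataFrame:
    """Per-environment bin fractions in every applicable weighting.

    Emits count-mode fractions per (environment, domain, dataset_type),
    depth-weighted fractions per (environment, domain) for metagenomes,
    and domain-combined per-environment rows (domain and dataset_type
    "all") used by the census stage — depth-weighted when scaffold depths
    exist, count-based otherwise (metatranscriptomes have no depths).
    """
    classifications = io.read_tsv(classifications_tsv)
    metadata = io.read_metadata(metadata_tsv)
    obs = build_observations(classifications, metadata)
    blocks = []
    grouped = count_fractions(obs, by=["environment", "domain", "dataset_type"])
    blocks.append(grouped)
    meta_obs = obs[obs["dataset_type"] == "metagenome"]
    if len(meta_obs) and meta_obs["read_depth"].notna().all():
        dw = depth_weighted_fractions(meta_obs, by=["environment", "domain"])
        dw.insert(2, "dataset_type", "metagenome")
        blocks.append(dw)
    combined = []
    for env, group in obs.groupby("environment", sort=True):
        depths_ok = (group["dataset_type"] == "metagenome").all() \
            and group["read_depth"].notna().all()
        if depths_ok:
            block = depth_weighted_fractions(group, by=["environment"])
        else:
            block = count_fractions(group, by=["environment"])
        combined.append(block)
    comb = pd.concat(combined, ignore_index=True)
    comb.insert(1, "domain", "all")
    comb.insert(2, "dataset_type", "all")
    profiles = pd.concat(blocks + [comb], ignore_index=True)
    io.write_tsv(profiles, out_tsv)
    return profiles


def stage_census(profiles_tsv, out_tsv, out_json,
                 cell_totals_tsv=None,
                 copy_model: CopyNumberModel | None = None):
    """Extrapolate the domain-combined fractions to global cell counts."""
    profiles = io.read_tsv(profiles_tsv)
    sel = profiles[(profiles["domain"] == "all") & (profiles["dataset_type"] == "all")]
    if sel.empty:
        raise DataError("profiles table has no domain-combined rows")
    totals = load_cell_totals(cell_totals_tsv)
    result = census_from_profiles(sel, totals, copy_model)
    io.write_tsv(result.to_frame(), out_tsv)
    Path(out_json).write_text(result.headline_json())
    return result


def stage_rank(classifications_tsv, metadata_tsv, out_tsv,
               abundance_mode: str = "count", n: int = 10) -> pd.DataFrame:
    """Top-n genus rank abundance per environment."""
    classifications = io.read_tsv(classifications_tsv)
    metadata = io.read_metadata(metadata_tsv)
    obs = build_observations(classifications, metadata)
    ranked = top_n(genus_abundances(obs, abundance_mode), n=n)
    io.write_tsv(ranked, out_tsv)
    return ranked


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages in order and write a manifest.

    Returns the mapping of artifact names to paths. A stage failure is
    re-raised with the stage name prepended.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for name in OUTPUT_FILES}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except MicrocensusError as err:
            raise type(err)(f"stage {name!r}: {err}") from err

    _stage("search", stage_search, config.queries_fasta, config.cultured_fasta,
           paths["hits.tsv"], config.alignment)
    if config.environmental_fasta:
        _stage("search_env", stage_search_env, config.queries_fasta,
               config.environmental_fasta, paths["hits.tsv"], paths["hits_env.tsv"],
               config.alignment, config.qc.chimera_alignment_fraction)
        hits_env = paths["hits_env.tsv"]
    else:
        hits_env = None
    _stage("qc", stage_qc, config.queries_fasta, config.metadata_tsv,
           paths["hits.tsv"], hits_env, paths["qc_report.tsv"],
           paths["qc_summary.json"], config.qc)
    _stage("classify", stage_classify, paths["hits.tsv"], paths["qc_report.tsv"],
           paths["classifications.tsv"], config.cutoffs)
    _stage("aggregate", stage_aggregate, paths["classifications.tsv"],
           config.metadata_tsv, paths["profiles.tsv"])
    _stage("census", stage_census, paths["profiles.tsv"], paths["census.tsv"],
           paths["census_headline.json"], config.cell_totals_tsv,
           config.copy_model)
    _stage("rank", stage_rank, paths["classifications.tsv"], config.metadata_tsv,
           paths["rank_abundance.tsv"])

    manifest = {
        "config_sha256": sha256_text(config.to_yaml()),
        "seed": config.seed,
        "outputs": {
            name: sha256_file(p) for name, p in sorted(paths.items()) if p.exists()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest.json"] = out / "manifest.json"
    return paths
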