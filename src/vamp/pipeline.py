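"""End-to-end orchestration: screen -> cluster -> ecology -> amg -> hostlink -> pnps.

All inter-stage state passes through documented files, so real tool outputs
(predictor score tables, BLAST fragments, SNP tables) can be substituted for
synthetic ones stage by stage. Each stage can be skipped when its outputs
already exist from an external source.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from vamp import amg as amg_mod
from vamp import ecology as eco_mod
from vamp import hostlink as host_mod
from vamp import selection as sel_mod
from vamp import viruscall as vc_mod
from vamp import votu as votu_mod
from vamp.synthdata import read_bundle

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and stage parameters for a full pipeline run."""

    bundle_dir: str = ""
    out_dir: str = "vamp_out"
    seed: int = 0
    # viruscall
    contaminant_k: int = 21
    contaminant_tau: float = 0.5
    # votu
    min_ani: float = 95.0
    min_af: float = 0.80
    # ecology
    permutations: int = 999
    permanova_grouping: str = "site"
    # amg
    amg_window: int = 5
    trim_min_run: int = 3
    trim_host_frac: float = 0.7
    # hostlink
    hostlink_k: int = 21
    hostlink_threshold: float = 3.0
    crispr_max_mismatch: int = 1
    spacer_min_len: int = 25
    # stage toggles
    stages: tuple[str, ...] = ("screen", "cluster", "ecology", "amg", "hostlink", "pnps")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Report (not raise) missing files, out-of-range parameters, absent seeds."""
    report: list[str] = []
    if not config.bundle_dir:
        report.append("bundle_dir not set")
    elif not Path(config.bundle_dir).is_dir():
        report.append(f"bundle_dir does not exist: {config.bundle_dir}")
    else:
        for fname in ("contigs.fasta", "scores.tsv", "genes.tsv", "samples.tsv"):
            if not (Path(config.bundle_dir) / fname).is_file():
                report.append(f"missing input file: {fname}")
    if config.seed is None:
        report.append("seed not set")
    if not 0 < config.min_af <= 1:
        report.append(f"min_af={config.min_af} outside (0, 1]")
    if not 0 <= config.min_ani <= 100:
        report.append(f"min_ani={config.min_ani} outside [0, 100]")
    if not 0 <= config.contaminant_tau <= 1:
        report.append(f"contaminant_tau={config.contaminant_tau} outside [0, 1]")
    if config.permutations < 1:
        report.append("permutations must be >= 1")
    unknown = set(config.stages) - {"screen", "cluster", "ecology", "amg", "hostlink", "pnps"}
    if unknown:
        report.append(f"unknown stages: {sorted(unknown)}")
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages in order over a bundle directory.

    Returns the run manifest (also written as manifest.json in out_dir):
    config snapshot, per-output checksums, and stage counts.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = read_bundle(config.bundle_dir)
    counts: dict[str, int] = {"contigs_in": len(bundle.contigs)}

    # ---- screen ------------------------------------------------------------
    calls_path = out / "virus_calls.tsv"
    if "screen" in config.stages:
        records = vc_mod.read_score_table(Path(config.bundle_dir) / "scores.tsv")
        try:
            calls = [vc_mod.classify_virus(r) for r in records]
        except vc_mod.ScoreValidationError as exc:
            raise StageError("screen", str(exc)) from exc
        flags = vc_mod.screen_contaminants(
            {c.contig_id: bundle.contigs[c.contig_id] for c in calls if c.is_virus},
            {},
            k=config.contaminant_k,
            tau=config.contaminant_tau,
        )
        calls = [
            vc_mod.VirusCall(
                c.contig_id, c.is_virus, c.criteria_met, flags.get(c.contig_id, False), c.eligible
            )
            for c in calls
        ]
        vc_mod.calls_to_frame(calls).to_csv(calls_path, sep="\t", index=False)
    calls_df = pd.read_csv(calls_path, sep="\t")
    virus_ids = [
        str(r.contig_id)
        for r in calls_df.itertuples()
        if r.is_virus and r.eligible and not r.contaminant
    ]
    counts["viruses_called"] = len(virus_ids)
    logger.info("screen: %d / %d contigs called viral", len(virus_ids), len(bundle.contigs))

    # ---- cluster -----------------------------------------------------------
    clusters_path = out / "votus.tsv"
    lengths = {c: len(s) for c, s in bundle.contigs.items() if c in set(virus_ids)}
    if "cluster" in config.stages:
        frags = votu_mod.read_fragment_table(Path(config.bundle_dir) / "fragments.tsv")
        frags = [f for f in frags if f.query_id in lengths and f.target_id in lengths]
        anis = votu_mod.pairwise_ani_from_fragments(frags, lengths)
        edges = votu_mod.build_edges(anis, min_ani=config.min_ani, min_af=config.min_af)
        clusters = votu_mod.greedy_cluster(lengths, edges)
        votu_mod.clusters_to_frame(clusters).to_csv(clusters_path, sep="\t", index=False)
    clusters_df = pd.read_csv(clusters_path, sep="\t")
    counts["votus"] = len(clusters_df)
    logger.info("cluster: %d vOTUs from %d viral contigs", len(clusters_df), len(virus_ids))

    # ---- ecology -----------------------------------------------------------
    meta = bundle.sample_metadata.set_index("sample_id")
    depth_wide = pd.DataFrame(
        {s: df.set_index("feature_id")["mean_depth"] for s, df in bundle.depth.items()}
    ).fillna(0.0)
    votu_abund = None
    if "ecology" in config.stages:
        norm = eco_mod.normalize_coverage(depth_wide, meta["library_bases"])
        reps = set(clusters_df["representative_id"].astype(str))
        votu_abund = norm.loc[[f for f in norm.index if f in reps]]
        votu_abund.rename_axis("feature_id").to_csv(out / "votu_abundance.tsv", sep="\t")
        try:
            part = eco_mod.partition_presence(
                votu_abund, meta[config.permanova_grouping], grouping=config.permanova_grouping
            )
            dist = eco_mod.bray_curtis(votu_abund)
            res = eco_mod.permanova(
                dist,
                meta.loc[dist.index, config.permanova_grouping],
                n_permutations=config.permutations,
                seed=config.seed,
            )
            eco_rows = {
                "grouping": config.permanova_grouping,
                "pseudo_F": res.pseudo_F,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "pct_shared_all_groups": part.pct_in_all,
                "pct_unique_one_group": part.pct_in_one,
            }
        except ValueError as exc:
            raise StageError("ecology", str(exc)) from exc
        pd.DataFrame([eco_rows]).to_csv(out / "ecology_summary.tsv", sep="\t", index=False)
        counts["ecology_features"] = len(votu_abund)

    # ---- amg ---------------------------------------------------------------
    amg_path = out / "amg_calls.tsv"
    if "amg" in config.stages:
        pmap = amg_mod.load_default_pathway_map()
        genes = bundle.gene_annotations()
        by_contig: dict[str, list] = {}
        for g in genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        all_calls = []
        for cid in sorted(by_contig):
            if cid not in set(virus_ids):
                continue
            all_calls.extend(
                amg_mod.curate_contig(
                    by_contig[cid],
                    pmap,
                    window=config.amg_window,
                    min_run=config.trim_min_run,
                    host_frac=config.trim_host_frac,
                )
            )
        amg_mod.calls_to_frame(all_calls).to_csv(amg_path, sep="\t", index=False)
        counts["amg_candidates"] = len(all_calls)
        counts["amgs_accepted"] = sum(c.status == "accepted" for c in all_calls)
        logger.info(
            "amg: %d candidates, %d accepted", counts["amg_candidates"], counts["amgs_accepted"]
        )

    # ---- hostlink ----------------------------------------------------------
    pred_path = out / "host_predictions.tsv"
    if "hostlink" in config.stages:
        mags = {
            m: {
                "sequence": bundle.mag_seqs[m],
                "trnas": bundle.mag_trnas.get(m, []),
                "spacers": bundle.mag_spacers.get(m, []),
            }
            for m in bundle.mag_seqs
        }
        viruses = {v: bundle.contigs[v] for v in virus_ids}
        evidence = host_mod.score_pairs(
            viruses,
            mags,
            k=config.hostlink_k,
            max_mismatch=config.crispr_max_mismatch,
            spacer_min_len=config.spacer_min_len,
        )
        preds = host_mod.aggregate_predictions(evidence, threshold=config.hostlink_threshold)
        host_mod.predictions_to_frame(preds).to_csv(pred_path, sep="\t", index=False)
        counts["host_links"] = sum(1 for v in preds.values() if v)

    # ---- pnps --------------------------------------------------------------
    if "pnps" in config.stages:
        snps = [
            sel_mod.SnpRecord(str(r.CHROM), int(r.POS), str(r.REF), str(r.ALT))
            for r in bundle.variants.itertuples(index=False)
        ]
        results = []
        for gid, seq in bundle.amg_gene_seqs.items():
            gene = sel_mod.CodingGene(gid, seq)
            results.append(sel_mod.pnps(gene, [s for s in snps if s.gene_id == gid]))
        sel_mod.results_to_frame(results).to_csv(out / "pnps.tsv", sep="\t", index=False)
        counts["pnps_genes"] = len(results)

    manifest = {
        "config": asdict(config),
        "counts": counts,
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
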