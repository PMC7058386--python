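"""End-to-end orchestration: config, stages, outputs and summary report.

The pipeline composes the analysis stages in order: annotation parsing and
feature derivation, receptor-gene exclusion, expression summaries
(TPM/FPKM), the differential-abundance filter with 3'UTR-binding flags,
the splicing-event filter with deduplication, binding-window
classification and NMD flagging, and finally z-score regulon clustering
over the union of hits from the three pairwise comparisons.  Every
threshold comes from the config; defaults are the study's stated values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import abundance, clip, regulon, splicing, windows
from .annotation import derive_features, exclude_receptor_genes, parse_gtf

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


@dataclass
class Thresholds:
    padj: float = 0.05
    log2fc: float = 0.5
    fpkm_floor: float = 1.0
    fdr: float = 0.05
    dpsi: float = 0.1
    min_junction_reads: int = 80
    window_size: int = 500
    n_clusters: int = 4
    pattern_margin: float = 0.5

    def __post_init__(self):
        for name in ("padj", "log2fc", "fpkm_floor", "fdr", "dpsi",
                     "min_junction_reads", "window_size", "pattern_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class Comparison:
    name: str
    condition_1: str
    condition_2: str
    de_table: Path
    events: dict  # event_type -> path


@dataclass
class PipelineConfig:
    annotation: Path
    clusters: Path
    counts: Path
    libraries: Path
    gene_lengths: Path
    comparisons: list[Comparison]
    thresholds: Thresholds = field(default_factory=Thresholds)
    outdir: Path = Path("results")
    target_genotype: str | None = None  # default: condition_1 of first comparison

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config; relative paths resolve against the file's folder."""
        path = Path(path)
        base = path.parent

        def p(raw_path) -> Path:
            raw_path = Path(raw_path)
            return raw_path if raw_path.is_absolute() else base / raw_path

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        comps = [
            Comparison(
                name=name,
                condition_1=c["condition_1"],
                condition_2=c["condition_2"],
                de_table=p(c["de_table"]),
                events={t: p(pth) for t, pth in c["events"].items()},
            )
            for name, c in sorted(raw["comparisons"].items())
        ]
        return cls(
            annotation=p(raw["annotation"]),
            clusters=p(raw["clusters"]),
            counts=p(raw["counts"]),
            libraries=p(raw["libraries"]),
            gene_lengths=p(raw["gene_lengths"]),
            comparisons=comps,
            thresholds=Thresholds(**raw.get("thresholds", {})),
            outdir=p(raw.get("outdir", "results")),
            target_genotype=raw.get("target_genotype"),
        )


@dataclass
class PipelineReport:
    summary: dict
    de_results: dict          # comparison name -> DiffExprResult
    as_events: dict           # comparison name -> list of kept SpliceEvent
    binding_calls: dict       # comparison name -> {event_id: BindingCall}
    gene_regulon: regulon.RegulonResult | None
    event_regulon: regulon.RegulonResult | None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # abort with the stage name
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage and write per-comparison tables plus summary.json.

    Outputs under ``config.outdir``: per-comparison up/down gene lists
    (with 3'UTR-bound flags), filtered + deduplicated event tables (with
    bound and NMD flags), regulon membership tables, and a summary JSON of
    the headline counts.  Re-running with identical config and inputs is
    byte-identical.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    ann = _stage("annotation")(parse_gtf)(config.annotation)
    idx = _stage("annotation")(derive_features)(ann)
    clusters = _stage("clip")(clip.load_clusters)(config.clusters)

    counts, metadata, lengths = _stage("expression")(_load_expression)(config)
    genotype_of = metadata["genotype"].to_dict()
    counts, removed_receptor = _stage("expression")(_drop_receptor)(counts, ann)
    fpkm = _stage("expression")(abundance.compute_fpkm)(counts, lengths.loc[counts.index])
    mean_fpkm = abundance.genotype_means(fpkm, genotype_of)
    tpm = abundance.compute_tpm(counts, lengths.loc[counts.index])
    mean_tpm = abundance.genotype_means(tpm, genotype_of)

    de_results, utr3_flags = {}, {}
    for comp in config.comparisons:
        de_results[comp.name] = _stage(f"differential:{comp.name}")(_run_de)(
            comp, ann, idx, clusters, mean_fpkm, th, out, utr3_flags
        )

    as_kept, binding_calls, nmd_flags = {}, {}, {}
    for comp in config.comparisons:
        kept, calls, nmd = _stage(f"splicing:{comp.name}")(_run_splicing)(
            comp, ann, clusters, mean_fpkm, th, out
        )
        as_kept[comp.name] = kept
        binding_calls[comp.name] = calls
        nmd_flags[comp.name] = nmd

    target = config.target_genotype or config.comparisons[0].condition_1
    other = _second_knockout(config, target)

    gene_reg = _stage("regulon:genes")(_gene_regulon)(
        de_results, counts, genotype_of, th, target, other, out
    )
    event_reg = _stage("regulon:events")(_event_regulon)(
        as_kept, config, metadata, genotype_of, th, target, other, out
    )

    summary = _summarise(
        config, de_results, utr3_flags, as_kept, binding_calls, nmd_flags,
        gene_reg, event_reg, mean_tpm, removed_receptor,
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return PipelineReport(summary, de_results, as_kept, binding_calls, gene_reg, event_reg)


def _load_expression(config: PipelineConfig):
    counts = pd.read_csv(config.counts, sep="\t", index_col="gene_id")
    metadata = pd.read_csv(config.libraries, sep="\t", index_col="library")
    lengths = pd.read_csv(config.gene_lengths, sep="\t", index_col="gene_id")["length"]
    missing = [c for c in counts.columns if c not in metadata.index]
    if missing:
        raise ValueError(f"libraries without metadata: {missing}")
    return counts, metadata.loc[counts.columns], lengths


def _drop_receptor(counts: pd.DataFrame, ann):
    table = counts.rename_axis("gene_id").reset_index()
    filtered, removed = exclude_receptor_genes(table, ann)
    log.info("excluded %d antigen-receptor genes", len(removed))
    return filtered.set_index("gene_id"), removed


def _run_de(comp, ann, idx, clusters, mean_fpkm, th, out, utr3_flags):
    de = abundance.read_deseq_table(comp.de_table)
    de, _ = exclude_receptor_genes(de, ann)
    result = abundance.filter_differential_genes(
        de, mean_fpkm,
        abundance.DiffExprThresholds(padj=th.padj, log2fc=th.log2fc,
                                     fpkm_floor=th.fpkm_floor),
    )
    for direction, table in (("up", result.up), ("down", result.down)):
        flags = []
        for gid in table["gene_id"]:
            if gid not in utr3_flags:
                bound, _sup = (clip.gene_3utr_bound(gid, clusters, idx)
                               if gid in ann else (False, []))
                utr3_flags[gid] = bound
            flags.append(int(utr3_flags[gid]))
        table = table.assign(utr3_bound=flags)
        table.to_csv(out / f"genes_{comp.name}_{direction}.tsv", sep="\t",
                     index=False, na_rep="NA")
    log.info("%s: %d up / %d down (missing padj: %d)",
             comp.name, len(result.up), len(result.down), result.n_missing_padj)
    return result


def _run_splicing(comp, ann, clusters, mean_fpkm, th, out):
    sth = splicing.SpliceFilterThresholds(
        fdr=th.fdr, dpsi=th.dpsi, fpkm_floor=th.fpkm_floor,
        min_junction_reads=th.min_junction_reads,
    )
    kept_all, calls, nmd = [], {}, {}
    rows = []
    for etype, path in sorted(comp.events.items()):
        events = splicing.load_events(path, etype)
        kept, reasons = splicing.filter_events(events, mean_fpkm, sth)
        kept = splicing.deduplicate_events(kept)
        log.info("%s %s: %d/%d events kept (%s)",
                 comp.name, etype, len(kept), len(events), reasons)
        for ev in kept:
            call = windows.classify_bound(ev, clusters, size=th.window_size)
            calls[ev.event_id] = call
            flag = splicing.flag_nmd(ev, ann, included=True)
            nmd[ev.event_id] = flag
            rows.append({
                "event_id": ev.event_id, "event_type": etype, "gene_id": ev.gene_id,
                "chrom": ev.chrom, "strand": ev.strand,
                "inc_level_difference": ev.inc_level_difference, "fdr": ev.fdr,
                "bound": int(call.bound), "n_hit_clusters": len({c.name for c, _ in call.hits}),
                "hit_window_roles": ";".join(call.hit_roles),
                "nmd_inclusion": "NA" if flag is None else int(flag),
            })
        kept_all.extend(kept)
    pd.DataFrame(rows, columns=[
        "event_id", "event_type", "gene_id", "chrom", "strand",
        "inc_level_difference", "fdr", "bound", "n_hit_clusters",
        "hit_window_roles", "nmd_inclusion",
    ]).to_csv(out / f"events_{comp.name}.tsv", sep="\t", index=False)
    return kept_all, calls, nmd


def _second_knockout(config, target):
    genotypes = {c.condition_1 for c in config.comparisons} | {
        c.condition_2 for c in config.comparisons
    }
    others = sorted(genotypes - {target})
    # the "other" knockout is whichever non-target genotype is compared
    # against both remaining genotypes; fall back to the first alternative
    for g in others:
        appearances = sum(g in (c.condition_1, c.condition_2) for c in config.comparisons)
        if appearances >= 2 and g != target:
            return g
    return others[0] if others else target


def _gene_regulon(de_results, counts, genotype_of, th, target, other, out):
    union = sorted(set().union(*(r.gene_ids for r in de_results.values())))
    union = [g for g in union if g in counts.index]
    if len(union) < th.n_clusters:
        log.warning("too few differential genes (%d) for clustering", len(union))
        return None
    sf = abundance.size_factors(counts)
    norm = counts.div(sf, axis=1)
    z = regulon.zscore_rows(norm.loc[union])
    result = regulon.cluster_rows(z, n_clusters=th.n_clusters)
    regulon.call_cluster_patterns(result, genotype_of, margin=th.pattern_margin,
                                  target=target, other=other)
    regulon.membership_frame(result).to_csv(out / "regulon_genes.tsv", sep="\t", index=False)
    return result


def _event_regulon(as_kept, config, metadata, genotype_of, th, target, other, out):
    psi = _psi_by_library(as_kept, config, metadata)
    psi = psi.dropna()
    if len(psi) < th.n_clusters:
        log.warning("too few differential events (%d) for clustering", len(psi))
        return None
    z = regulon.zscore_rows(psi)
    result = regulon.cluster_rows(z, n_clusters=th.n_clusters)
    regulon.call_cluster_patterns(result, genotype_of, margin=th.pattern_margin,
                                  target=target, other=other)
    regulon.membership_frame(result).to_csv(out / "regulon_events.tsv", sep="\t", index=False)
    return result


def _psi_by_library(as_kept, config, metadata) -> pd.DataFrame:
    """Reassemble an event x library PSI matrix from the comparison tables.

    Replicate PSI lists in each table follow the library order of their
    condition in the metadata; a library seen in several comparisons keeps
    its first-seen values (the generator and rMATS both report the same
    underlying replicates).
    """
    lib_by_geno: dict[str, list[str]] = {}
    for lib, row in metadata.iterrows():
        lib_by_geno.setdefault(row["genotype"], []).append(lib)
    cells: dict[str, dict[str, float]] = {}
    for comp in config.comparisons:
        kept = as_kept.get(comp.name, [])
        for ev in kept:
            row = cells.setdefault(ev.event_id, {})
            for geno, psis in ((comp.condition_1, ev.inc1), (comp.condition_2, ev.inc2)):
                libs = lib_by_geno.get(geno, [])
                for lib, v in zip(libs, psis):
                    row.setdefault(lib, float("nan") if v is None else v)
    frame = pd.DataFrame.from_dict(cells, orient="index")
    return frame.reindex(columns=list(metadata.index)).sort_index()


def _summarise(config, de_results, utr3_flags, as_kept, binding_calls, nmd_flags,
               gene_reg, event_reg, mean_tpm, removed_receptor) -> dict:
    per_comp = {}
    for comp in config.comparisons:
        de = de_results[comp.name]
        kept = as_kept[comp.name]
        calls = binding_calls[comp.name]
        nmd = nmd_flags[comp.name]
        de_ids = sorted(de.gene_ids)
        n_bound_genes = sum(utr3_flags.get(g, False) for g in de_ids)
        by_type = {}
        for etype in sorted({ev.event_type for ev in kept} | set(comp.events)):
            evs = [ev for ev in kept if ev.event_type == etype]
            by_type[etype] = len(evs)
        n_bound = sum(calls[ev.event_id].bound for ev in kept)
        per_comp[comp.name] = {
            "genes_increased": len(de.up),
            "genes_decreased": len(de.down),
            "genes_missing_padj": de.n_missing_padj,
            "fraction_de_genes_utr3_bound": round(n_bound_genes / len(de_ids), 4)
            if de_ids else None,
            "events_significant_by_type": by_type,
            "events_significant_total": len(kept),
            "fraction_events_bound": round(n_bound / len(kept), 4) if kept else None,
            "events_nmd_flagged": sum(1 for v in nmd.values() if v is True),
        }
    geno_pairs = {}
    genos = list(mean_tpm.columns)
    for i, a in enumerate(genos):
        for b in genos[i + 1:]:
            geno_pairs[f"{a}_vs_{b}"] = round(
                abundance.spearman_log_tpm(mean_tpm[a], mean_tpm[b]), 4
            )
    summary = {
        "comparisons": per_comp,
        "n_receptor_genes_excluded": len(removed_receptor),
        "spearman_log_tpm": geno_pairs,
        "gene_regulon": _regulon_summary(gene_reg),
        "event_regulon": _regulon_summary(event_reg),
    }
    return summary


def _regulon_summary(result):
    if result is None:
        return None
    patterns = result.cluster_patterns
    return {
        "n_rows": int(len(result.row_labels)),
        "clusters": [
            {"cluster_id": int(r.cluster_id), "n_rows": int(r.n_rows), "pattern": r.pattern}
            for r in patterns.itertuples()
        ],
    }
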