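"""End-to-end orchestration: simulate -> preprocess -> peaks -> annotate ->
borders -> co-binding -> motifs, with summary tables mirroring the study's
reporting (per-condition peak counts and gene associations, gene-relative
category distribution, Venn overlap counts, washout retention ratios,
border-pair statistics, midpoint co-positioning distributions, motif
fractions and summit profiles).

All randomness derives from ``SimConfig.seed``; two runs with the same
configuration produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (GeneModel, annotate_peaks, category_counts,
                       genes_with_peaks)
from .borders import BorderPair, find_border_pairs, write_border_pairs
from .cobind import (CoverageDistribution, count_ratio, coverage_table,
                     distribution_similarity, midpoint_coverage, overlap_sets)
from .config import CONDITIONS, FACTORS, PipelineConfig, SimConfig
from .intervals import GenomicInterval
from .motifs import load_pwm, motif_enrichment_fraction, motif_frequency_profile
from .peaks import (Peak, ProfileSet, build_stop_profile, call_peaks,
                    write_narrowpeak)
from .preprocess import (GenomeIndex, RawRead, process_reads, write_filter_log,
                         write_tags_bed)
from .simulate import (ReadRecord, TruthTable, plant_sites, simulate_genome,
                       simulate_input_reads, simulate_nexus_reads,
                       synthetic_gene_models, write_fasta, write_fastq)


def _to_raw(records: List[ReadRecord]) -> List[RawRead]:
    return [RawRead(r.read_id, r.sequence,
                    [ord(c) - 33 for c in r.quality]) for r in records]


@dataclass
class SampleResult:
    factor: str
    condition: str
    tags: pd.DataFrame
    log: Dict[str, int]
    profiles: ProfileSet
    peaks: List[Peak] = field(default_factory=list)


@dataclass
class PipelineResult:
    sim: SimConfig
    pipe: PipelineConfig
    genome: str
    truth: TruthTable
    genes: List[GeneModel]
    samples: Dict[Tuple[str, str], SampleResult]
    input_profiles: ProfileSet
    table1: pd.DataFrame = None
    categories: pd.DataFrame = None
    multiplicity: pd.DataFrame = None
    venn: pd.DataFrame = None
    retention: pd.DataFrame = None
    border_pairs: Dict[str, List[BorderPair]] = field(default_factory=dict)
    border_stats: pd.DataFrame = None
    copositioning: pd.DataFrame = None
    similarity: pd.DataFrame = None
    motif_fractions: pd.DataFrame = None
    motif_profile: pd.DataFrame = None

    def peaks_for(self, factor: str, condition: str) -> List[Peak]:
        return self.samples[(factor, condition)].peaks


def run_pipeline(sim: SimConfig, pipe: PipelineConfig,
                 outdir: Optional[Path] = None,
                 conditions: Tuple[str, ...] = CONDITIONS,
                 factors: Tuple[str, ...] = FACTORS,
                 write_reads: bool = False) -> PipelineResult:
    """Run the whole analysis on one simulated experiment.

    When ``outdir`` is given, per-stage files (FASTA/FASTQ/BED/narrowPeak/
    TSV) and a JSON manifest are written there.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        for sub in ("fastq", "tags", "peaks", "tables"):
            (out / sub).mkdir(parents=True, exist_ok=True)

    # --- simulate -------------------------------------------------------
    genome = simulate_genome(sim)
    genome, truth = plant_sites(genome, sim)
    genes_df = synthetic_gene_models(sim)
    genes = [GeneModel(r["gene_id"], r["chrom"],
                       GenomicInterval(r["chrom"], int(r["start"]),
                                       int(r["end"])), r["strand"])
             for _, r in genes_df.iterrows()]
    index = GenomeIndex.from_genome(genome, sim.chrom)
    sizes = index.chrom_sizes()
    if out is not None:
        write_fasta(genome, out / "genome.fa", sim.chrom)
        truth.write_tsv(out / "truth.tsv")
        truth.write_bed(out / "truth.bed")
        genes_df.to_csv(out / "genes.bed", sep="\t", index=False, header=False)

    # --- input control --------------------------------------------------
    input_records, _ = simulate_input_reads(genome, sim)
    input_tags, input_log = process_reads(_to_raw(input_records), index, pipe)
    input_profiles = build_stop_profile(input_tags, sizes)
    manifest_counts = {"input": input_log}
    if out is not None and write_reads:
        write_fastq(input_records, out / "fastq" / "input.fastq")

    # --- IP samples -----------------------------------------------------
    samples: Dict[Tuple[str, str], SampleResult] = {}
    for factor in factors:
        for cond in conditions:
            records, _ = simulate_nexus_reads(genome, truth, cond, factor, sim)
            tags, log = process_reads(_to_raw(records), index, pipe)
            profiles = build_stop_profile(tags, sizes)
            pk = call_peaks(profiles, input_profiles, pipe)
            samples[(factor, cond)] = SampleResult(factor, cond, tags, log,
                                                   profiles, pk)
            manifest_counts[f"{factor}_{cond}"] = log
            if out is not None:
                stem = f"{factor}_{cond}"
                if write_reads:
                    write_fastq(records, out / "fastq" / f"{stem}.fastq")
                write_tags_bed(tags, out / "tags" / f"{stem}.bed")
                write_filter_log(log, out / "tags" / f"{stem}.filterlog.tsv")
                write_narrowpeak(pk, out / "peaks" / f"{stem}.narrowPeak")

    result = PipelineResult(sim=sim, pipe=pipe, genome=genome, truth=truth,
                            genes=genes, samples=samples,
                            input_profiles=input_profiles)

    # --- per-condition counts and gene associations (Table 1 analogue) ---
    rows = []
    annotated: Dict[Tuple[str, str], pd.DataFrame] = {}
    for factor in factors:
        for cond in conditions:
            pk = samples[(factor, cond)].peaks
            ann = annotate_peaks(pk, genes, pipe)
            annotated[(factor, cond)] = ann
            per_gene, _ = genes_with_peaks(ann)
            rows.append({"condition": cond, "factor": factor,
                         "peaks": len(pk), "genes_with_peaks": len(per_gene)})
    result.table1 = pd.DataFrame(rows)

    # --- category distribution and multiplicity (Fig 1c/d analogue) ------
    cat_rows, mult_rows = [], []
    for factor in factors:
        for cond in conditions:
            counts = category_counts(annotated[(factor, cond)])
            for cat, n in counts.items():
                cat_rows.append({"factor": factor, "condition": cond,
                                 "category": cat, "count": int(n)})
        _, (single, multiple) = genes_with_peaks(
            annotated[(factor, "CORT")] if "CORT" in conditions
            else annotated[(factor, conditions[0])])
        mult_rows.append({"factor": factor, "single": single,
                          "multiple": multiple})
    result.categories = pd.DataFrame(cat_rows)
    result.multiplicity = pd.DataFrame(mult_rows)

    # --- overlap (Venn) and retention dynamics ---------------------------
    venn_rows = []
    if len(factors) == 2:
        for cond in conditions:
            a = samples[(factors[0], cond)].peaks
            b = samples[(factors[1], cond)].peaks
            ov = overlap_sets(a, b)
            venn_rows.append({
                "condition": cond,
                f"{factors[0]}_total": len(a), f"{factors[1]}_total": len(b),
                f"{factors[0]}_overlapping": ov.n_overlapping_a,
                f"{factors[1]}_overlapping": ov.n_overlapping_b})
    result.venn = pd.DataFrame(venn_rows)

    ret_rows = []
    for factor in factors:
        for num_cond, den_cond in (("washout", "CORT"), ("vehicle", "CORT")):
            if num_cond not in conditions or den_cond not in conditions:
                continue
            den = len(samples[(factor, den_cond)].peaks)
            num = len(samples[(factor, num_cond)].peaks)
            pct = count_ratio(num, den) if den > 0 else float("nan")
            ret_rows.append({"factor": factor, "numerator": num_cond,
                             "denominator": den_cond, "count_num": num,
                             "count_den": den, "percent": pct})
    result.retention = pd.DataFrame(ret_rows)

    # --- border pairs (CORT condition) ------------------------------------
    bcond = "CORT" if "CORT" in conditions else conditions[0]
    bstat_rows = []
    for factor in factors:
        s = samples[(factor, bcond)]
        pairs, unpaired = find_border_pairs(s.profiles[sim.chrom], s.peaks,
                                            pipe)
        result.border_pairs[factor] = pairs
        widths = [p.width for p in pairs]
        bstat_rows.append({
            "factor": factor, "condition": bcond, "pairs": len(pairs),
            "unpaired_borders": len(unpaired),
            "width_min": int(min(widths)) if widths else 0,
            "width_median": float(np.median(widths)) if widths else 0.0,
            "width_max": int(max(widths)) if widths else 0})
        if out is not None:
            write_border_pairs(pairs, out / "tables"
                               / f"border_pairs_{factor}.bed")
    result.border_stats = pd.DataFrame(bstat_rows)

    # --- midpoint co-positioning (factors[1] as reference, e.g. GR) ------
    if len(factors) == 2:
        ref_factor, other = factors[1], factors[0]
        ref_peaks = samples[(ref_factor, bcond)].peaks
        regions_ref = [p.interval for p in result.border_pairs[ref_factor]]
        regions_other = [p.interval for p in result.border_pairs[other]]
        if not regions_ref:
            regions_ref = [p.interval for p in ref_peaks]
        if not regions_other:
            regions_other = [p.interval
                             for p in samples[(other, bcond)].peaks]
        d_ref, d_other = midpoint_coverage(ref_peaks, regions_ref,
                                           regions_other, pipe)
        result.copositioning = coverage_table(d_ref, d_other).rename(
            columns={"count_A": f"count_{ref_factor}",
                     "count_B": f"count_{other}",
                     "norm_A": f"norm_{ref_factor}",
                     "norm_B": f"norm_{other}"})
        if d_ref.total > 0 and d_other.total > 0:
            jsd, corr = distribution_similarity(d_ref, d_other)
        else:
            jsd, corr = float("nan"), float("nan")
        result.similarity = pd.DataFrame([{
            "reference": ref_factor, "other": other,
            "jsd_nats": jsd, "pearson_r": corr}])

    # --- motif analyses (CORT peaks) --------------------------------------
    pwm = load_pwm("GRE")
    genome_map = {sim.chrom: genome}
    mf_rows = []
    for factor in factors:
        pk = samples[(factor, bcond)].peaks
        for window in pipe.motif_windows:
            frac = motif_enrichment_fraction(pk, genome_map, pwm, window)
            mf_rows.append({"factor": factor, "condition": bcond,
                            "motif": pwm.name, "window": window,
                            "fraction": round(frac, 4), "n_peaks": len(pk)})
    result.motif_fractions = pd.DataFrame(mf_rows)
    prof_factor = factors[0]
    result.motif_profile = motif_frequency_profile(
        samples[(prof_factor, bcond)].peaks, genome_map, pwm,
        max(pipe.motif_windows))

    # --- persist summaries ------------------------------------------------
    if out is not None:
        tables = {
            "table1_counts.tsv": result.table1,
            "categories.tsv": result.categories,
            "gene_multiplicity.tsv": result.multiplicity,
            "venn_counts.tsv": result.venn,
            "retention_ratios.tsv": result.retention,
            "border_stats.tsv": result.border_stats,
            "copositioning.tsv": result.copositioning,
            "copositioning_similarity.tsv": result.similarity,
            "motif_fractions.tsv": result.motif_fractions,
            "motif_profile.tsv": result.motif_profile,
        }
        for name, df in tables.items():
            if df is not None:
                df.to_csv(out / "tables" / name, sep="\t", index=False)
        _write_manifest(out, sim, pipe, manifest_counts)
    return result


def _write_manifest(out: Path, sim: SimConfig, pipe: PipelineConfig,
                    counts: Dict[str, Dict[str, int]]) -> None:
    digests = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digests[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()).hexdigest()[:16]
    manifest = {
        "version": __version__,
        "seed": sim.seed,
        "sim_config": asdict(sim),
        "pipeline_config": asdict(pipe),
        "stage_counts": counts,
        "file_digests": digests,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
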