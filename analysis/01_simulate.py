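#!/usr/bin/env python
"""Generate the synthetic dual-receptor ChIP-nexus experiment.

Writes a 200 kb genome with 100 planted binding sites (58% carrying the GRE
consensus, 66% co-bound), ChIP-nexus FASTQ reads for MR and GR under
vehicle / CORT / washout, an input control, gene models and the ground-truth
tables, under results/sim/.
"""

import argparse
from pathlib import Path

from nexuskit.config import CONDITIONS, FACTORS, SimConfig
from nexuskit.simulate import (plant_sites, simulate_genome,
                               simulate_input_reads, simulate_nexus_reads,
                               synthetic_gene_models, write_fasta, write_fastq)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    sim = SimConfig(seed=args.seed)
    out = args.outdir
    (out / "fastq").mkdir(parents=True, exist_ok=True)

    genome = simulate_genome(sim)
    genome, truth = plant_sites(genome, sim)
    write_fasta(genome, out / "genome.fa", sim.chrom)
    with open(out / "genome.chrom.sizes", "w") as fh:
        fh.write(f"{sim.chrom}\t{sim.genome_length}\n")
    truth.write_tsv(out / "truth.tsv")
    truth.write_bed(out / "truth.bed")
    synthetic_gene_models(sim).to_csv(out / "genes.bed", sep="\t",
                                      index=False, header=False)

    n_total = 0
    for factor in FACTORS:
        for cond in CONDITIONS:
            records, _ = simulate_nexus_reads(genome, truth, cond, factor, sim)
            write_fastq(records, out / "fastq" / f"{factor}_{cond}.fastq")
            n_total += len(records)
            print(f"  {factor} {cond:8s}: {len(records):6d} reads "
                  f"({len(truth.bound_sites(cond, factor))} bound sites)")
    records, _ = simulate_input_reads(genome, sim)
    write_fastq(records, out / "fastq" / "input.fastq")
    print(f"  input control : {len(records):6d} reads")
    print(f"\n{len(truth)} sites planted on {sim.genome_length} bp; "
          f"{n_total} IP reads total -> {out}")


if __name__ == "__main__":
    main()
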