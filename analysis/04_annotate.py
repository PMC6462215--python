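#!/usr/bin/env python
"""Annotate CORT-condition peaks relative to gene models: within a gene,
within 5 kb up-/downstream, or intergenic; count genes with single vs
multiple associated binding sites.  Writes annotation tables under
results/tables/.
"""

import argparse
from pathlib import Path

import pandas as pd

from nexuskit.annotate import (annotate_peaks, category_counts,
                               genes_with_peaks, read_gene_models)
from nexuskit.config import FACTORS, PipelineConfig
from nexuskit.peaks import read_narrowpeak


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--peakdir", type=Path, default=Path("results/peaks"))
    ap.add_argument("--outdir", type=Path, default=Path("results/tables"))
    args = ap.parse_args()

    pipe = PipelineConfig()
    genes = read_gene_models(args.simdir / "genes.bed")
    args.outdir.mkdir(parents=True, exist_ok=True)

    cat_rows, mult_rows = [], []
    for factor in FACTORS:
        peaks = read_narrowpeak(args.peakdir / f"{factor}_CORT.narrowPeak")
        ann = annotate_peaks(peaks, genes, pipe)
        ann.to_csv(args.outdir / f"annotated_{factor}_CORT.tsv", sep="\t",
                   index=False)
        counts = category_counts(ann)
        for cat, n in counts.items():
            cat_rows.append({"factor": factor, "category": cat,
                             "count": int(n),
                             "pct": round(100 * n / len(peaks), 1)})
        per_gene, (single, multiple) = genes_with_peaks(ann)
        mult_rows.append({"factor": factor, "genes_with_peaks": len(per_gene),
                          "single": single, "multiple": multiple})
        intergenic = counts["intergenic"] / len(peaks)
        print(f"  {factor}: {len(peaks)} peaks, {len(per_gene)} genes, "
              f"{100 * intergenic:.0f}% intergenic, "
              f"{multiple} genes with multiple sites")
    pd.DataFrame(cat_rows).to_csv(args.outdir / "categories.tsv", sep="\t",
                                  index=False)
    pd.DataFrame(mult_rows).to_csv(args.outdir / "gene_multiplicity.tsv",
                                   sep="\t", index=False)


if __name__ == "__main__":
    main()
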