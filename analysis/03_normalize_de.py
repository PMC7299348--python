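"""Normalization and moderated differential expression.

TMM factors, the CPM>1 expression gate, voom precision weights, the
weighted group-means model with empirical-Bayes moderation, and all 21
pairwise contrasts. Full contrast tables go to scratch/pipeline/; a
summary of universe sizes and the variance prior goes to results/.
"""

import argparse
import json
from pathlib import Path

from sgnseq.io import read_counts, read_sample_sheet, read_lengths
from sgnseq.normalization import tmm_factors
from sgnseq.classify import Thresholds, expression_gate
from sgnseq.diffexp import voom_transform, fit_model, ebayes_moderate, pairwise_contrasts

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    args = ap.parse_args()

    data = ROOT / "scratch" / "pipeline"
    design = read_sample_sheet(data / "samples.tsv")
    m = read_counts(data / "counts.tsv", design, lengths=read_lengths(data / "lengths.tsv"))
    th = Thresholds()

    nf = tmm_factors(m)
    universe = expression_gate(m, th, "de_universe")
    voomed = voom_transform(m.subset_genes(universe), nf)
    fit = ebayes_moderate(fit_model(voomed))
    contrasts = pairwise_contrasts(fit)
    contrasts.to_csv(data / "contrasts.tsv", sep="\t", index=False)

    summary = {
        "n_genes": len(m.gene_ids),
        "de_universe": len(universe),
        "n_contrasts": int(contrasts.contrast.nunique()),
        "prior_df": round(float(fit.prior_df), 3),
        "prior_var": round(float(fit.prior_var), 4),
        "tmm_factor_range": [round(float(nf.factors.min()), 3),
                             round(float(nf.factors.max()), 3)],
    }
    (ROOT / "results" / "03_de_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"gated {summary['de_universe']}/{summary['n_genes']} genes; "
          f"{summary['n_contrasts']} contrasts; prior df {summary['prior_df']}")


if __name__ == "__main__":
    main()
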