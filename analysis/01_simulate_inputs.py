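"""Generate the synthetic study inputs.

Writes a two-group biomarker panel (2,549 genes, n = 10 per group, 5%
planted DE) and a three-population UMI matrix with a signature-high,
condition-enriched population under results/synthetic/.
"""

import json
from pathlib import Path

import fbrmech.io as fio
from fbrmech.synthetic import simulate_panel_counts, simulate_umi_matrix

SEED = 20230925
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_panel_counts(
        n_genes=2549, n_per_group=10, frac_de=0.05, lfc=1.5,
        dispersion=0.2, seed=SEED,
    )
    fio.write_panel_counts(cm, OUT / "panel_counts.csv", OUT / "sample_sheet.csv",
                           seed=SEED)
    (OUT / "panel_truth.json").write_text(
        json.dumps({"de_gene_ids": truth.de_gene_ids,
                    "log2_fold_change": 1.5}, indent=2))
    print(f"panel: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples, "
          f"{len(truth.de_gene_ids)} planted DE genes")

    umi, sc_truth = simulate_umi_matrix(
        n_cells_per_pop=[400, 400, 250], n_genes=800, signature_size=25,
        planted_uplift=1.0, mito_frac_range=(0.0, 0.08), seed=SEED + 1,
    )
    fio.write_umi_matrix(umi, OUT / "umi", seed=SEED + 1)
    (OUT / "umi_truth.json").write_text(
        json.dumps({"signature_gene_ids": sc_truth.signature_gene_ids,
                    "planted_uplift": 1.0}, indent=2))
    print(f"umi: {umi.n_cells} cells x {umi.n_genes} genes "
          f"({umi.counts.nnz} nonzeros), signature-high population pop0")


if __name__ == "__main__":
    main()
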