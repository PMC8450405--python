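"""Recompute tumor-vs-normal GAG fold changes from real UCSC Xena matrices.

Not runnable offline: download the TCGA/GTEx "RSEM expected_count
(DESeq2 standardized)"-era TPM matrices (gene symbol x sample,
log2(TPM+0.001)) and a tumor/normal sample manifest from xenabrowser.net
for the tissue of interest, then:

    python analysis/06_xena_reproduction.py TUMOR.tsv NORMAL.tsv out.tsv

Both inputs are decoded with the Xena transform (2^x - 0.001), harmonized
against the knowledge base and compared with the standard pipeline.
Published reference points for pancreatic tumor vs normal: CHST3 4.0,
CHST15 3.5, VCAN 4.8, DCN 1.5; dataset-version drift of ±0.1 or more is
expected across Xena releases.
"""

import sys
from pathlib import Path

from gagmap import (
    ExpressionMatrix,
    compare_cohorts,
    load_kb,
    read_tpm_table,
    xena_log_to_tpm,
)


def main(tumor_path: str, normal_path: str, out_path: str) -> None:
    kb = load_kb()

    def load(path: str, group: str) -> ExpressionMatrix:
        m = read_tpm_table(path, "rows")
        values = xena_log_to_tpm(m.values)
        return ExpressionMatrix(values, {s: group for s in m.sample_ids})

    tumor = load(tumor_path, "tumor")
    normal = load(normal_path, "normal")
    result = compare_cohorts(kb, tumor, normal)
    result.to_frame().to_csv(out_path, sep="\t", index=False)
    for gene in ("CHST3", "CHST15", "VCAN", "DCN", "DSE"):
        try:
            rec = result.record(gene, "gene")
        except KeyError:
            continue
        print(f"{gene}: fc {rec.fc:.2f} ({rec.direction}, p={rec.p_value:.1e})")
    print(f"wrote {out_path}")


if __name__ == "__main__":
    if len(sys.argv) != 4:
        sys.exit(__doc__)
    main(*sys.argv[1:])
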