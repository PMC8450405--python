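"""Render the five pathway-category diagrams colored by the comparison.

Each reaction arrow is pink when its tumor/normal (median+1) fold change
exceeds 1.5, green below 0.667, gray otherwise. Requires the outputs of
03/04. Writes SVG files under results/figures/.
"""

from pathlib import Path

import pandas as pd

from gagmap import load_kb, render_pathway
from gagmap.comparison import ComparisonResult, FoldChangeRecord

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    kb = load_kb()
    df = pd.read_csv(OUT / "cohort_comparison.tsv", sep="\t")
    records = [
        FoldChangeRecord(
            target_id=row.target_id, level=row.level,
            median_tumor=row.median_tumor, median_normal=row.median_normal,
            fc=row.fc, fc_raw=row.fc_raw, direction=row.direction,
            p_value=row.p_value, n_tumor=row.n_tumor, n_normal=row.n_normal,
        )
        for row in df.itertuples()
    ]
    result = ComparisonResult(records)
    figdir = OUT / "figures"
    figdir.mkdir(exist_ok=True)
    for category in kb.categories:
        svg = render_pathway(kb, result, category)
        path = figdir / f"pathway_{category.lower()}.svg"
        path.write_text(svg)
        n_up = svg.count('class="reaction up"')
        n_down = svg.count('class="reaction down"')
        print(f"{category:15s} -> {path.name}: {n_up} up, {n_down} down arrows")


if __name__ == "__main__":
    main()
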