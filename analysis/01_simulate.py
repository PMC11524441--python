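#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analysis scripts.

Writes a fold-change compendium with five planted related datasets, a pair
of coupled differential-expression tables, a curated annotation and a
predicted-target gene set to results/sim/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from oasig import (
    SimConfig,
    generate_annotation_and_targets,
    generate_compendium,
    generate_linked_de_tables,
    significant_sets,
    write_annotation,
    write_de_table,
    write_gmt,
    write_profile_matrix,
)

SEED = 20240
OUT = ROOT / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    # compendium at search scale; DE tables and annotation at full study scale
    cfg = SimConfig(seed=SEED, n_genes=2000, n_datasets=800, n_related=5)
    cfg_de = SimConfig(seed=SEED)
    print(f"simulating with seed={SEED}: compendium {cfg.n_datasets} datasets x "
          f"{cfg.n_genes} genes; DE tables {cfg_de.n_genes} genes")

    comp, query, related = generate_compendium(cfg)
    write_profile_matrix(comp, OUT / "compendium.tsv", OUT / "metadata.tsv")
    query.values.rename("log2fc").rename_axis("gene").to_csv(
        OUT / "query_profile.tsv", sep="\t", float_format="%.10g"
    )

    ta, tb, de_truth = generate_linked_de_tables(cfg_de)
    write_de_table(ta, OUT / "de_table_a.tsv")
    write_de_table(tb, OUT / "de_table_b.tsv")

    up, down = significant_sets(ta)
    ann, targets, ann_truth = generate_annotation_and_targets(cfg_de, up, down, ta.genes)
    write_annotation(ann, OUT / "annotation.tsv")
    write_gmt([targets], OUT / "targets.gmt")

    truth = {
        "seed": SEED,
        "related_dataset_ids": related,
        "n_de_genes": len(de_truth["de_genes"]),
        "decorrelation": de_truth["decorrelation"],
        "n_up_table_a": len(up),
        "n_down_table_a": len(down),
        **ann_truth,
    }
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(f"planted related datasets: {', '.join(related)}")
    print(f"table A significant genes: {len(up)} up, {len(down)} down")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
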