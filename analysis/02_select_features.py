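"""Rank candidate predictors and fix the network's feature set.

One-hot expands the gestational-age and EFW families, ranks every binary
candidate by chi-square and mutual information with composite morbidity,
prunes Jaccard-redundant near-duplicates, searches k-of-m feature
combinations by logistic-regression AUC, and adds the forced clinical
includes (HDP, term birth, EFW <3rd, EFW 3-9th).
"""
import json
import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
analysis_config = import_module("00_config").analysis_config

from contextrisk.pipeline import stage_select


def main() -> None:
    cfg = analysis_config()
    artifacts = stage_select(cfg)
    selected = json.loads(Path(artifacts["selected_features"]).read_text())
    print(f"Best {len(selected['best_subset'])}-feature logistic subset "
          f"(in-sample AUC {selected['best_subset_auc']:.3f}):")
    for f in selected["best_subset"]:
        print(f"  {f}")
    print(f"Final network features ({len(selected['final_features'])}):")
    for f in selected["final_features"]:
        print(f"  {f}")


if __name__ == "__main__":
    main()
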