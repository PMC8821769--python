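"""Generate the two synthetic gradient scenarios used by the analyses.

Writes, per scenario, the three pipeline inputs (Newick tree, site x
species occurrence CSV, site table CSV) plus a provenance JSON under
results/fixtures/<preset>/.  The latitudinal-like scenario is a single
species pool filtered along a smooth climate gradient over 36 sites;
the longitudinal-like scenario adds two basal clades biased toward
opposite ends of a 34-site transect.
"""

import json
import pathlib

from bdtt import phylo_io
from bdtt.synthetic_data import PRESETS, make_scenario

SEED = 42
ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    for preset in sorted(PRESETS):
        out = ROOT / "results" / "fixtures" / preset
        out.mkdir(parents=True, exist_ok=True)
        tree, occ, sites, config = make_scenario(preset, seed=SEED)
        phylo_io.write_newick(tree, str(out / "tree.nwk"))
        phylo_io.write_occurrence(occ, str(out / "occ.csv"))
        phylo_io.write_sites(sites, str(out / "sites.csv"))
        (out / "scenario.json").write_text(
            json.dumps({"preset": preset, **config.__dict__}, indent=2)
        )
        n_pairs = occ.n_sites * (occ.n_sites - 1) // 2
        print(
            f"{preset}: {tree.n_tips} species on a {config.root_age:g}-Myr tree, "
            f"{occ.n_sites} sites ({n_pairs} site pairs), "
            f"mean richness {occ.presence().sum(axis=1).mean():.1f} -> {out}"
        )


if __name__ == "__main__":
    main()
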