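"""Parsimony character evolution of the eight families.

Reconstructs ancestral presence/absence of HLIP, OHP1, OHP2, SEP, ELIP,
RedCAP, LHC and PSBS on the bundled consensus plastid species tree
(rooted on Gloeobacter) and reports each family's origin node and loss
count.
"""

from pathlib import Path

from lhc_origins import bundled_character_matrix, bundled_species_tree
from lhc_origins.trees_tests import fitch, infer_origins

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    tree = bundled_species_tree()
    chars = bundled_character_matrix()
    states = fitch(tree, chars)
    origins = infer_origins(states)
    origins.to_csv(RESULTS / "family_origins.tsv", sep="\t", index=False)
    print(origins.to_string(index=False))
    print("\nreading: HLIP is ancestral (cyanobacterial), OHP2 and SEP "
          "arose in the Plantae ancestor, LHC in the red/green ancestor, "
          "OHP1, ELIP and PSBS at the green-lineage base, RedCAP at the "
          "red-lineage base")


if __name__ == "__main__":
    main()
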