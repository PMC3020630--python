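"""lhc-origins: evolution of the extended light-harvesting-complex
protein superfamily.

Rule-based family classification of chlorophyll-binding (CB) proteins
from profile HMMs, transmembrane architecture and sequence motifs;
four-cluster likelihood mapping of CB helix blocks to test independent
versus common origins of the LHC and PSBS families; topology tests; and
parsimony character evolution — exercised end to end on a synthetic
sequence-evolution simulator with internal gene-duplication scenarios.
"""

from importlib import resources

__version__ = "0.1.0"


def bundled_species_tree():
    """The bundled consensus plastid species tree (rooted on Gloeobacter).

    Synthetic stand-in encoding only relationships stated for the
    fifteen study organisms: cyanobacteria basal, glaucophytes the
    deepest Plantae branch, diatoms nested with the red algae.
    """
    from .seqio import read_newick

    path = resources.files("lhc_origins.data") / "species_tree.nwk"
    return read_newick(path.read_text())


def bundled_character_matrix():
    """Bundled presence/absence of the eight families over the 15 taxa.

    Synthetic stand-in encoding the published taxonomic-distribution
    statements (e.g. SEP absent only from Cyanidioschyzon among the
    twelve eukaryotes; ELIP and PSBS confined to the green lineage).
    """
    import io

    from .seqio import read_character_matrix

    path = resources.files("lhc_origins.data") / "family_characters.tsv"
    return read_character_matrix(io.StringIO(path.read_text()))
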