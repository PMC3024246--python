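"""The dlx cluster evolutionary scenario as a packaged character matrix.

Presence/absence/missing states for CNEs of the dlx bi-gene clusters and
for dlx gene-repertoire characters across seven osteichthyans, together
with the species tree they are scored on.  The states transcribe the
observed cross-species conservation pattern: which lineages share each
intergenic (``I``) or flanking (``F``) element, which dlx paralogs each
genome retains, and where a region is unscorable (``?`` — e.g. the anole
lizard's dlx5-dlx6 flanking region is largely unsequenced).

The dlx ``b``-series paralogs were born at the teleost-specific genome
duplication (TSGD); their origin is therefore dated a priori to the
teleost stem branch (``gene_origins``) rather than inferred from extant
presence — indeed dlx1b/5b/6b survive in no sequenced teleost genome and
would otherwise be vacuous characters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io import CharacterMatrix, SpeciesTree, parse_newick

__all__ = ["DlxScenario", "dlx_scenario", "SCENARIO_NEWICK"]

#: Anole lizard (tetrapod outgroup), zebrafish, and the percomorphs:
#: pufferfishes (Takifugu, Tetraodon) vs stickleback + (medaka, cichlid).
SCENARIO_NEWICK = (
    "(anole,(zebrafish,((Takifugu,Tetraodon)pufferfishes,"
    "(stickleback,(medaka,A.burtoni)medaka_cichlid)smc)Percomorpha)Teleostei)"
    "Osteichthyes;"
)

TAXA = (
    "anole",
    "zebrafish",
    "Takifugu",
    "Tetraodon",
    "stickleback",
    "medaka",
    "A.burtoni",
)

# Shorthand support patterns (anole, zebrafish, Takifugu, Tetraodon,
# stickleback, medaka, A.burtoni), in TAXA order.
_ALL = ("1", "1", "1", "1", "1", "1", "1")
_TELEOSTS = ("0", "1", "1", "1", "1", "1", "1")
_PERCOMORPHS = ("0", "0", "1", "1", "1", "1", "1")
_SMC = ("0", "0", "0", "0", "1", "1", "1")  # stickleback-medaka-cichlid

_CHARACTERS: dict[str, tuple[str, ...]] = {
    # --- intergenic CNEs ---------------------------------------------------
    # the a/b sub-elements of one dlx1-dlx2 element: the spanning element is
    # a stickleback-medaka-cichlid novelty, while its b part is older and was
    # lost specifically in the cichlid lineage
    "I12.3a": _SMC,
    "I12.3b": ("0", "1", "1", "1", "1", "1", "0"),
    "I12.3ab": _SMC,
    # conserved in every surveyed osteichthyan (and matched even outside them)
    "I12.5": _ALL,
    # percomorph-only elements, absent from zebrafish
    "I12.7": _PERCOMORPHS,
    "I34.1": _PERCOMORPHS,
    "I34.2": _PERCOMORPHS,
    "I34.4": _PERCOMORPHS,
    "I34.5": _PERCOMORPHS,
    "I34.6": _PERCOMORPHS,
    # stickleback-medaka-cichlid novelty in the dlx5-dlx6 intergenic region
    "I56.2": _SMC,
    # ancestral element lost in the zebrafish lineage
    "I56.5": ("1", "0", "1", "1", "1", "1", "1"),
    "I56.6a": _PERCOMORPHS,
    "I56.7": _PERCOMORPHS,
    # --- flanking CNEs -----------------------------------------------------
    # conserved in all analyzed species; the anole region is not completely
    # sequenced, so its state is unknown rather than absent
    "F56.9": ("?", "1", "1", "1", "1", "1", "1"),
    # stickleback-medaka-cichlid novelty; anole flanking region unscorable
    "F56.10": ("?", "0", "0", "0", "1", "1", "1"),
    # --- gene repertoire ---------------------------------------------------
    # TSGD-born duplicates lost in the teleost stem lineage itself
    "dlx1b": ("0", "0", "0", "0", "0", "0", "0"),
    "dlx5b": ("0", "0", "0", "0", "0", "0", "0"),
    "dlx6b": ("0", "0", "0", "0", "0", "0", "0"),
    # retained only by otocephalans; lost on the percomorph stem
    "dlx2b": ("0", "1", "0", "0", "0", "0", "0"),
    # lost in the zebrafish (Cypriniformes) lineage and in the cichlid lineage
    "dlx3a": ("0", "0", "1", "1", "1", "1", "0"),
    # lost in the medaka lineage
    "dlx4a": ("0", "1", "1", "1", "1", "0", "1"),
}

# all b-series paralogs (and the a-series TSGD co-duplicates scored here)
# originate on the teleost stem
_TSGD_GENES = ("dlx1b", "dlx5b", "dlx6b", "dlx2b", "dlx3a", "dlx4a")


@dataclass(frozen=True)
class DlxScenario:
    matrix: CharacterMatrix
    tree: SpeciesTree
    gene_origins: Mapping[str, str]


def dlx_scenario() -> DlxScenario:
    """Packaged matrix + tree + a-priori gene origins for the dlx scenario."""
    states = {
        char: dict(zip(TAXA, column)) for char, column in _CHARACTERS.items()
    }
    matrix = CharacterMatrix.from_dict(
        states, taxa=list(TAXA), characters=list(_CHARACTERS)
    )
    tree = parse_newick(SCENARIO_NEWICK)
    origins = {gene: "Teleostei" for gene in _TSGD_GENES}
    return DlxScenario(matrix=matrix, tree=tree, gene_origins=origins)
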