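"""Tissue category codes shared by every stage of the pipeline.

A labeled villus stack assigns one small-integer category per voxel. The
codes below are fixed and documented rather than inferred from data; a
category map is always passed explicitly when reading stacks from disk.

Category sets:

* *villous tissue* is every category except the intervillous (maternal
  blood) space — the denominator for "% of villous volume".
* the *stromal compartment* is the four stromal constituents
  (extracellular matrix, vesicles, stellate cells, macrophages) — the
  denominator for "% of stroma volume". Pericytes, endothelium and
  capillary lumen are villous but extra-stromal.
"""

from __future__ import annotations

from types import MappingProxyType

INTERVILLOUS_SPACE = 0
SYNCYTIOTROPHOBLAST = 1
CYTOTROPHOBLAST = 2
STROMA_ECM = 3
STELLATE_CELL = 4
MACROPHAGE = 5
PERICYTE = 6
ENDOTHELIAL_CELL = 7
CAPILLARY_LUMEN = 8
VESICLE = 9

#: Default code -> name mapping for villus stacks.
CATEGORY_MAP = MappingProxyType(
    {
        INTERVILLOUS_SPACE: "intervillous_space",
        SYNCYTIOTROPHOBLAST: "syncytiotrophoblast",
        CYTOTROPHOBLAST: "cytotrophoblast",
        STROMA_ECM: "stroma_ecm",
        STELLATE_CELL: "stellate_cell",
        MACROPHAGE: "macrophage",
        PERICYTE: "pericyte",
        ENDOTHELIAL_CELL: "endothelial_cell",
        CAPILLARY_LUMEN: "capillary_lumen",
        VESICLE: "vesicle",
    }
)

NAME_TO_CODE = MappingProxyType({v: k for k, v in CATEGORY_MAP.items()})

#: Categories counted as villous tissue (everything but intervillous space).
VILLOUS_CATEGORIES = frozenset(
    name for name in NAME_TO_CODE if name != "intervillous_space"
)

#: The stromal compartment: its four constituents sum to 100% of stroma.
STROMAL_CATEGORIES = frozenset(
    {"stroma_ecm", "vesicle", "stellate_cell", "macrophage"}
)

#: Stromal *cells* for vesicle-contact classification.
STROMAL_CELL_CATEGORIES = frozenset({"stellate_cell", "macrophage"})

#: Partner categories reported by contact analysis.
CONTACT_PARTNER_CATEGORIES = frozenset(
    {
        "stellate_cell",
        "macrophage",
        "pericyte",
        "endothelial_cell",
        "syncytiotrophoblast",  # proxy for the trophoblast basal lamina
        "vesicle",
    }
)
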