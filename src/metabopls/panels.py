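"""Published COPD-vs-OSAS biomarker panels for the three biofluid blocks.

The reported VIP-PLS-DA and SR-PLS-DA metabolite selections from the
COPD/OSAS multi-biofluid NMR study, transcribed with block-qualified
canonical names (``"<block>__<metabolite>"``; unknown resonances keep their
chemical shift, e.g. ``"ebc__unk2_d2.90"``).  These printed lists are inputs
to the overlap arithmetic: e.g. the EBC VIP and SR panels share 7 of the 16
EBC metabolites (44 %), the serum panels 12 of 31 (39 %), and the combined
EBC+urine model panels 8 variables.

The reported urine overlap count (5) differs from the intersection of the
printed urine lists (6 shared names); the discrepancy is preserved here as
transcribed and the urine overlap is therefore not used as a check anywhere.
"""

from __future__ import annotations

from .evaluate import OverlapStat, overlap_stats

__all__ = ["BLOCK_SIZES", "PUBLISHED_PANELS", "published_overlap"]

BLOCK_SIZES = {"ebc": 16, "serum": 31, "urine": 27}

PUBLISHED_PANELS: dict[tuple[str, ...], dict[str, list[str]]] = {
    ("ebc",): {
        "vip": [
            "ebc__propylene_glycol", "ebc__ethanol", "ebc__3-hydroxyisovalerate",
            "ebc__acetone", "ebc__methanol", "ebc__unk2_d2.90",
            "ebc__unk3_d3.57", "ebc__unk4_d7.07", "ebc__formate",
        ],
        "sr": [
            "ebc__propylene_glycol", "ebc__ethanol", "ebc__3-hydroxyisovalerate",
            "ebc__methanol", "ebc__unk2_d2.90", "ebc__unk3_d3.57",
            "ebc__isopropanol", "ebc__formate",
        ],
    },
    ("serum",): {
        "vip": [
            "serum__l1", "serum__l3", "serum__l4", "serum__l6",
            "serum__isoleucine", "serum__unk1_d1.11", "serum__unk2_d2.22",
            "serum__unk3_d4.26", "serum__acetate", "serum__glutamine",
            "serum__choline", "serum__gpc+apc", "serum__histidine",
            "serum__phenylalanine",
        ],
        "sr": [
            "serum__l2", "serum__l3", "serum__l4", "serum__l6",
            "serum__leucine", "serum__isoleucine", "serum__unk1_d1.11",
            "serum__unk2_d2.22", "serum__unk3_d4.26", "serum__lactate",
            "serum__acetate", "serum__nac1", "serum__nac2",
            "serum__glutamine", "serum__choline", "serum__histidine",
            "serum__phenylalanine",
        ],
    },
    ("urine",): {
        "vip": [
            "urine__isobutyrate", "urine__3-aminoisobutyrate",
            "urine__2-hydroxyisobutyrate", "urine__unk2_d2.35",
            "urine__nn-dimethylglycine", "urine__sn-glycero-3-phosphocholine",
            "urine__creatine", "urine__creatinine", "urine__xanthine",
            "urine__formate",
        ],
        "sr": [
            "urine__isobutyrate", "urine__methylsuccinate",
            "urine__3-hydroxyisovalerate", "urine__lactate",
            "urine__2-hydroxyisobutyrate", "urine__unk2_d2.35",
            "urine__nn-dimethylglycine", "urine__sn-glycero-3-phosphocholine",
            "urine__cis-aconitate", "urine__formate",
        ],
    },
    ("ebc", "urine"): {
        "vip": [
            "ebc__propylene_glycol", "ebc__ethanol", "ebc__3-hydroxyisovalerate",
            "ebc__unk2_d2.90", "ebc__methanol", "ebc__isopropanol", "ebc__formate",
            "urine__isobutyrate", "urine__3-aminoisobutyrate",
            "urine__2-hydroxyisobutyrate", "urine__unk2_d2.35",
            "urine__nn-dimethylglycine", "urine__sn-glycero-3-phosphocholine",
            "urine__creatine", "urine__creatinine",
            "urine__trimethylamine_n-oxide", "urine__xanthine", "urine__formate",
        ],
        "sr": [
            "ebc__propylene_glycol", "ebc__formate",
            "urine__isobutyrate", "urine__methylsuccinate",
            "urine__methylmalonate", "urine__3-hydroxyisovalerate",
            "urine__lactate", "urine__2-hydroxyisobutyrate", "urine__unk2_d2.35",
            "urine__nn-dimethylglycine", "urine__sn-glycero-3-phosphocholine",
            "urine__cis-aconitate", "urine__formate",
        ],
    },
}


def published_overlap(blocks: tuple[str, ...]) -> OverlapStat:
    """Overlap between the published VIP and SR panels of a block combination."""
    panels = PUBLISHED_PANELS[blocks]
    total = sum(BLOCK_SIZES[b] for b in blocks)
    return overlap_stats(panels["vip"], panels["sr"], total)
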