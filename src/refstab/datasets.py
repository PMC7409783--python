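"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["published_rankings", "published_recommendations"]


def published_rankings() -> pd.DataFrame:
    """Published per-method stability ranks/values for the four-species study.

    One row per (species, tissue, gene): geNorm, NormFinder and BestKeeper
    ranks and values plus the published comprehensive rank.
    """
    ref = resources.files("refstab.data") / "published_rankings.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


#: published per-panel reference-gene suggestions
PUBLISHED_RECOMMENDATIONS = {
    ("piceifrons", "head"): ["RIBL5", "Hsp70", "EF2"],
    ("piceifrons", "thorax"): ["RIBL5", "Hsp70", "GAPDH"],
    ("americana", "head"): ["Act5C", "EF2"],
    ("americana", "thorax"): ["RIBL5", "EF2"],
    ("cubense", "head"): ["Act5C", "Hsp70"],
    ("cubense", "thorax"): ["Hsp70", "Ann"],
    ("nitens", "head"): ["Ann", "Act5C"],
    ("nitens", "thorax"): ["Ann", "Arm"],
}


def published_recommendations() -> dict:
    return dict(PUBLISHED_RECOMMENDATIONS)
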