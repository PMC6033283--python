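"""Manifest of the targeted radiosensitivity code-set.

The assay emulated here is a custom nCounter-style panel of 248 genes:
235 endogenous analysis genes plus 13 housekeeping genes used only for
per-sample normalization, together with the platform's positive-control
spike ladder and negative-control background probes.  Gene membership is
annotated by source category (discovery screen, published radiosensitivity
signatures, literature, housekeeping); the category is descriptive only and
never enters any computation.
"""

from __future__ import annotations

import pandas as pd

PROBE_CLASSES = ("endogenous", "housekeeping", "positive_ctrl", "negative_ctrl")
SOURCE_CATEGORIES = (
    "discovery",
    "rsi",
    "rss",
    "tramm",
    "literature",
    "housekeeping",
    "control",
)

#: 13 housekeeping genes commonly used on nCounter code sets.
HOUSEKEEPING_GENES = [
    "ACTB", "CLTC", "GAPDH", "GUSB", "HPRT1", "MTO1", "PGK1",
    "PSMC4", "RPLP0", "SF3A1", "TBP", "TFRC", "TUBB",
]

#: Genes of the 10-gene rank-linear radiosensitivity surrogate score.
RSI_GENES = ["ABL1", "AR", "HDAC1", "IRF1", "JUN", "PAK2", "PRKCB", "RELA", "STAT1", "SUMO1"]

#: Immune-response gene set used for the immune score (geometric mean).
#: "RelA" in the source annotation maps to panel id RELA.
IMMUNE_GENES = ["IRF1", "IGKC", "STAT1", "OSMR", "CCL19", "RELA", "IRF8", "FGR", "TNFRSF1B", "C3"]

#: Proliferation score gene set (geometric mean).
PROLIFERATION_GENES = ["MKI67", "AURKA"]

#: Literature additions: receptors, proliferation, apoptosis, DNA repair,
#: hypoxia and related breast-cancer biology.
LITERATURE_GENES = [
    "ESR1", "PGR", "ERBB2", "MKI67", "AURKA", "FOXC1", "BCL2", "BRCA1",
    "BRCA2", "BIRC5", "MET", "HGF", "HIF1A", "EPAS1", "WRAP53",
]

POSITIVE_CONTROLS = [f"POS_{c}" for c in "ABCDEF"]
NEGATIVE_CONTROLS = [f"NEG_{c}" for c in "ABCDEFGH"]

# Named immune genes come from the discovery screen; the remaining discovery
# genes and the two published multi-gene signatures are placeholder ids
# (their true membership is not public at the gene level).
_DISCOVERY_NAMED = ["IGKC", "OSMR", "CCL19", "IRF8", "FGR", "TNFRSF1B", "C3"]
_N_DISCOVERY_TOTAL = 152
_N_RSS = 51
_N_TRAMM = 7


def default_manifest() -> pd.DataFrame:
    """Build the default 248-gene manifest (plus control probes).

    Returns a DataFrame with columns ``gene_id``, ``probe_class``,
    ``source_category``; 248 unique genes of which 13 are housekeeping,
    6 positive-control and 8 negative-control probes.
    """
    rows: list[tuple[str, str, str]] = []

    def add(genes, probe_class, category):
        for g in genes:
            rows.append((g, probe_class, category))

    discovery = _DISCOVERY_NAMED + [
        f"DSC{i:03d}" for i in range(1, _N_DISCOVERY_TOTAL - len(_DISCOVERY_NAMED) + 1)
    ]
    add(discovery, "endogenous", "discovery")
    add(RSI_GENES, "endogenous", "rsi")
    add([f"RSS{i:03d}" for i in range(1, _N_RSS + 1)], "endogenous", "rss")
    add([f"TRM{i:03d}" for i in range(1, _N_TRAMM + 1)], "endogenous", "tramm")
    add(LITERATURE_GENES, "endogenous", "literature")
    add(HOUSEKEEPING_GENES, "housekeeping", "housekeeping")
    add(POSITIVE_CONTROLS, "positive_ctrl", "control")
    add(NEGATIVE_CONTROLS, "negative_ctrl", "control")

    manifest = pd.DataFrame(rows, columns=["gene_id", "probe_class", "source_category"])
    validate_manifest(manifest)
    return manifest


def validate_manifest(manifest: pd.DataFrame) -> None:
    """Raise ``ValueError`` if the manifest violates its invariants."""
    required = {"gene_id", "probe_class", "source_category"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest["gene_id"].duplicated().any():
        dups = manifest.loc[manifest["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_ids in manifest: {dups}")
    bad = set(manifest["probe_class"]) - set(PROBE_CLASSES)
    if bad:
        raise ValueError(f"unknown probe classes: {sorted(bad)}")
    bad = set(manifest["source_category"]) - set(SOURCE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown source categories: {sorted(bad)}")
    n_hk = (manifest["probe_class"] == "housekeeping").sum()
    if n_hk < 1:
        raise ValueError("manifest needs at least one housekeeping probe")
    n_pos = (manifest["probe_class"] == "positive_ctrl").sum()
    if n_pos < 6:
        raise ValueError(f"manifest needs >=6 positive-control probes, found {n_pos}")


def genes_of_class(manifest: pd.DataFrame, probe_class: str) -> list[str]:
    """gene_ids of one probe class, in manifest order."""
    if probe_class not in PROBE_CLASSES:
        raise ValueError(f"unknown probe class {probe_class!r}")
    return manifest.loc[manifest["probe_class"] == probe_class, "gene_id"].tolist()
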