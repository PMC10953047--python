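"""Gene-panel registry and signature scores.

Whole-blood SLE expression signatures are summarised as *gene expression
scores*: for each annotated panel (two interferon-stimulated-gene scores,
plasmablast, neutrophil, myeloid lineage, inflammation and erythropoiesis
modules) the score of a sample is the median reflected ΔCt over the panel's
transcripts.  Panels carry the module annotations (M4.11, M5.15, ...) of the
published whole-blood microarray repertoires they were selected from.

The packaged default registry is *synthetic*: panel sizes match the published
counts (plasmablast 4, neutrophil 15, myeloid 17, inflammation 13,
erythropoiesis 11, plus 13 + 14 ISGs in the two IFN scores and 7 further
ISGs), but transcript membership is an illustrative stand-in for the
supplementary assay manifest and should be replaced with the user's own
panel file for real data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .qpcr import ExpressionMatrix

__all__ = [
    "GenePanel",
    "PanelRegistry",
    "ScoreTable",
    "default_registry",
    "load_panel_registry",
    "compute_scores",
    "SCORE_PANELS",
    "IFN_SCORE_A",
    "IFN_SCORE_B",
    "PLASMABLAST",
    "NEUTROPHIL",
    "MYELOID",
    "INFLAMMATION",
    "ERYTHROPOIESIS",
    "EXTRA_ISG",
]

IFN_SCORE_A = "IFN-Score-A"
IFN_SCORE_B = "IFN-Score-B"
PLASMABLAST = "plasmablast"
NEUTROPHIL = "neutrophil"
MYELOID = "myeloid"
INFLAMMATION = "inflammation"
ERYTHROPOIESIS = "erythropoiesis"
EXTRA_ISG = "extra-ISG"

#: Panels that yield a signature score.  ``extra-ISG`` transcripts are carried
#: in the matrix (and used in transcript-level clustering) but belong to no
#: score.
SCORE_PANELS: tuple[str, ...] = (
    IFN_SCORE_A,
    IFN_SCORE_B,
    PLASMABLAST,
    NEUTROPHIL,
    MYELOID,
    INFLAMMATION,
    ERYTHROPOIESIS,
)

#: Published panel sizes for the module-annotated scores.
EXPECTED_PANEL_SIZES: Mapping[str, int] = {
    PLASMABLAST: 4,
    NEUTROPHIL: 15,
    MYELOID: 17,
    INFLAMMATION: 13,
    ERYTHROPOIESIS: 11,
}


class RegistryError(ValueError):
    """Raised for malformed panel registries."""


@dataclass(frozen=True)
class GenePanel:
    """A named transcript panel with its source-module annotations."""

    name: str
    transcripts: tuple[str, ...]
    module_annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.transcripts) == 0:
            raise RegistryError(f"panel {self.name!r} is empty")
        if len(set(self.transcripts)) != len(self.transcripts):
            raise RegistryError(f"panel {self.name!r} has duplicate transcripts")

    def __len__(self) -> int:
        return len(self.transcripts)


@dataclass(frozen=True)
class PanelRegistry:
    """Ordered collection of gene panels keyed by panel name."""

    panels: Mapping[str, GenePanel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, panel in self.panels.items():
            if name != panel.name:
                raise RegistryError(f"panel key {name!r} != panel name {panel.name!r}")

    def __getitem__(self, name: str) -> GenePanel:
        return self.panels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.panels

    def __iter__(self):
        return iter(self.panels.values())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.panels)

    @property
    def score_panels(self) -> tuple[GenePanel, ...]:
        return tuple(p for p in self if p.name in SCORE_PANELS)

    def all_transcripts(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for panel in self:
            for t in panel.transcripts:
                seen.setdefault(t, None)
        return tuple(seen)

    def panel_of(self, transcript: str) -> str | None:
        for panel in self:
            if transcript in panel.transcripts:
                return panel.name
        return None

    def to_dict(self) -> dict:
        return {
            p.name: {
                "transcripts": list(p.transcripts),
                "modules": list(p.module_annotations),
            }
            for p in self
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PanelRegistry":
        panels: dict[str, GenePanel] = {}
        for name, entry in payload.items():
            if isinstance(entry, (list, tuple)):
                transcripts, modules = entry, ()
            else:
                transcripts = entry.get("transcripts", ())
                modules = entry.get("modules", ())
            if name in panels:
                raise RegistryError(f"duplicate panel name {name!r}")
            panels[name] = GenePanel(
                name=name,
                transcripts=tuple(transcripts),
                module_annotations=tuple(modules),
            )
        if not panels:
            raise RegistryError("registry defines no panels")
        return cls(panels=panels)


# Synthetic default manifest.  Sizes are the published counts; membership is
# an illustrative stand-in for the supplementary TaqMan list.
_DEFAULT_PANELS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    IFN_SCORE_A: (
        ("IFI27", "IFI44", "IFI44L", "IFI6", "RSAD2", "SIGLEC1", "USP18",
         "LY6E", "OAS1", "HERC5", "ISG15", "IFIT1", "IFIT3"),
        ("M1.2", "M3.4"),
    ),
    IFN_SCORE_B: (
        ("OAS2", "OAS3", "MX1", "MX2", "IFIH1", "DDX60", "EPSTI1", "HERC6",
         "IRF7", "SAMD9", "SAMD9L", "STAT1", "STAT2", "XAF1"),
        ("M3.4", "M5.12"),
    ),
    EXTRA_ISG: (
        ("BST2", "IFITM1", "IFITM3", "CXCL10", "DDX58", "ZBP1", "SOCS1"),
        (),
    ),
    PLASMABLAST: (
        ("JCHAIN", "MZB1", "TNFRSF17", "TXNDC5"),
        ("M4.11", "M7.7"),
    ),
    NEUTROPHIL: (
        ("CEACAM8", "DEFA4", "ELANE", "MPO", "CTSG", "LCN2", "LTF", "MMP8",
         "MMP9", "OLFM4", "CAMP", "BPI", "CEACAM6", "ARG1", "ORM1"),
        ("M5.15",),
    ),
    MYELOID: (
        ("CD14", "FCGR1A", "S100A8", "S100A9", "S100A12", "FPR1", "FPR2",
         "CLEC4D", "CLEC4E", "CLEC5A", "IL1R1", "IL1R2", "TLR2", "TLR4",
         "TREM1", "CSF3R", "MCEMP1"),
        ("M3.2", "M5.7"),
    ),
    INFLAMMATION: (
        ("IL1B", "IL6", "TNF", "PTX3", "SOD2", "IL18", "NLRP3", "CXCL8",
         "CCL2", "SERPINB1", "TNFAIP6", "PLAUR", "IL1RN"),
        ("M4.2",),
    ),
    ERYTHROPOIESIS: (
        ("ALAS2", "AHSP", "HBB", "HBD", "GATA1", "GYPA", "GYPB", "EPB42",
         "SLC4A1", "KLF1", "TFRC"),
        ("M2.3", "M3.1"),
    ),
}


def default_registry() -> PanelRegistry:
    """Packaged synthetic default registry (94 transcripts in 8 panels)."""
    return PanelRegistry.from_dict(
        {
            name: {"transcripts": transcripts, "modules": modules}
            for name, (transcripts, modules) in _DEFAULT_PANELS.items()
        }
    )


def load_panel_registry(path: str | Path) -> PanelRegistry:
    """Load a panel registry from a YAML or JSON file.

    The file maps panel name to either a transcript list or a mapping with
    ``transcripts`` and optional ``modules`` keys.  Warns when a
    module-annotated panel's size differs from the published count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(payload, Mapping):
        raise RegistryError(f"registry file {path} does not define a mapping")
    registry = PanelRegistry.from_dict(payload)
    for name, expected in EXPECTED_PANEL_SIZES.items():
        if name in registry and len(registry[name]) != expected:
            warnings.warn(
                f"panel {name!r} has {len(registry[name])} transcripts; "
                f"published count is {expected}",
                stacklevel=2,
            )
    return registry


@dataclass(frozen=True)
class ScoreTable:
    """Per-sample signature scores (reflected ΔCt units).

    ``scores`` is samples × panels; ``stratum`` (optional) is the ancestry
    stratum label per sample, aligned to ``scores.index``.
    """

    scores: pd.DataFrame
    stratum: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.stratum is not None and not self.scores.index.equals(self.stratum.index):
            raise ValueError("stratum index does not match score index")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.scores.index)

    @property
    def panels(self) -> tuple[str, ...]:
        return tuple(self.scores.columns)

    def __getitem__(self, panel: str) -> pd.Series:
        return self.scores[panel]

    def with_stratum(self, stratum: pd.Series) -> "ScoreTable":
        return ScoreTable(self.scores, stratum.reindex(self.scores.index))

    def save(self, path: str | Path) -> None:
        out = self.scores.copy()
        if self.stratum is not None:
            out.insert(0, "stratum", self.stratum)
        out.to_csv(path, index_label="sample")


def compute_scores(
    expr: ExpressionMatrix,
    registry: PanelRegistry,
    panels: Sequence[str] | None = None,
) -> ScoreTable:
    """Compute signature scores as panel medians of reflected ΔCt.

    For each panel the score of a sample is the median of that sample's
    expression values over the panel transcripts present in the matrix; an
    even number of values uses the mean of the two middle ones (ordinary
    mid-median).  Transcripts missing from the matrix are dropped with a
    warning; a panel with no matched transcript is an error.
    """
    names = tuple(panels) if panels is not None else tuple(
        n for n in registry.names if n in SCORE_PANELS
    )
    values = expr.to_frame()  # transcripts × samples
    out: dict[str, np.ndarray] = {}
    for name in names:
        panel = registry[name]
        present = [t for t in panel.transcripts if t in values.index]
        missing = [t for t in panel.transcripts if t not in values.index]
        if not present:
            raise RegistryError(f"panel {name!r}: no transcripts present in the matrix")
        if missing:
            warnings.warn(
                f"panel {name!r}: dropping {len(missing)} transcripts absent from "
                f"the matrix ({', '.join(missing[:5])}{'...' if len(missing) > 5 else ''})",
                stacklevel=2,
            )
        out[name] = values.loc[present].median(axis=0).to_numpy()
    frame = pd.DataFrame(out, index=pd.Index(values.columns, name="sample"))
    return ScoreTable(frame)
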