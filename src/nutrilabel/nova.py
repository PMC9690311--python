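"""NOVA degree-of-processing classification as a deterministic rule ladder.

NOVA assigns foods to four groups: 1 unprocessed or minimally processed,
2 processed culinary ingredients, 3 processed foods, 4 ultra-processed
products. Human raters resolve this by expert judgement over the ingredient
list; here the judgement is replaced by an auditable ladder over ingredient
*marker tags* attached to each record, evaluated in fixed order:

1. any ultra-processing marker (cosmetic additives, refined industrial
   ingredients) -> NOVA 4;
2. the record is a single culinary substance (it carries a
   culinary-substance tag) -> NOVA 2;
3. any processing marker (salting, canning, fermentation, ...) -> NOVA 3;
4. otherwise -> NOVA 1.

The marker vocabulary is shipped as data (``data/vocabulary.yaml``), closed
(unknown tags are errors) and versioned by content hash.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import yaml

from .model import FoodRecord

NOVA_CLASSES = (1, 2, 3, 4)


class UnknownMarkerError(ValueError):
    """A record carries a tag outside the closed vocabulary."""


@dataclass(frozen=True)
class MarkerVocabulary:
    """Three pairwise-disjoint tag sets driving the NOVA ladder."""

    up_markers: frozenset[str]
    processing_markers: frozenset[str]
    culinary_substances: frozenset[str]

    def __post_init__(self):
        sets = (self.up_markers, self.processing_markers, self.culinary_substances)
        names = ("up_markers", "processing_markers", "culinary_substances")
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(
                        f"{names[i]} and {names[j]} overlap: {sorted(overlap)}")

    @property
    def all_tags(self) -> frozenset[str]:
        return self.up_markers | self.processing_markers | self.culinary_substances

    @property
    def version(self) -> str:
        """Content hash so every logged verdict can cite its vocabulary."""
        payload = "|".join(",".join(sorted(s)) for s in (
            self.up_markers, self.processing_markers, self.culinary_substances))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True, slots=True)
class NovaResult:
    nova: int
    fired_rule: str
    evidence: frozenset[str]


def load_vocabulary(path=None) -> MarkerVocabulary:
    """Load a vocabulary file (YAML with the three tag lists); the packaged
    default when ``path`` is None."""
    if path is None:
        text = resources.files("nutrilabel.data").joinpath("vocabulary.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return MarkerVocabulary(
        up_markers=frozenset(raw["up_markers"]),
        processing_markers=frozenset(raw["processing_markers"]),
        culinary_substances=frozenset(raw["culinary_substances"]),
    )


def classify_nova(record: FoodRecord, vocab: MarkerVocabulary) -> NovaResult:
    """Run the four-rung ladder; deterministic in (record, vocabulary)."""
    unknown = record.markers - vocab.all_tags
    if unknown:
        raise UnknownMarkerError(
            f"unknown marker tag(s) on {record.food_id}: {', '.join(sorted(unknown))}")
    up = record.markers & vocab.up_markers
    if up:
        return NovaResult(4, "ultra_processing_marker", frozenset(up))
    culinary = record.markers & vocab.culinary_substances
    if culinary:
        return NovaResult(2, "single_culinary_substance", frozenset(culinary))
    processing = record.markers & vocab.processing_markers
    if processing:
        return NovaResult(3, "processing_marker", frozenset(processing))
    return NovaResult(1, "no_processing_evidence", frozenset())
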