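"""Genome-level cellulolytic-potential screening from CAZyme annotations.

A genome is a *candidate* cellulose degrader when it encodes all three
functional components of the canonical cellulolytic system:

* an endoglucanase (GH5 or GH8),
* an exo-acting / processive cellulase (GH48, GH6, GH7, GH9 or GH16),
* a beta-glucosidase (GH1 or GH3).

Candidates receive a baseline score of 1 point, plus up to three bonus
points for confidence-enhancing features: presence of an LPMO (AA9/AA10),
endoglucanase redundancy (>= 2 copies across GH5+GH8), and exoglucanase
redundancy (>= 2 copies across the exo families). Bonuses are layered on
the baseline, so a non-candidate genome scores 0 regardless of bonus
features (configurable via ``bonus_requires_baseline=False``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ENDO_FAMILIES",
    "EXO_FAMILIES",
    "BGLU_FAMILIES",
    "LPMO_FAMILIES",
    "CAZymeProfile",
    "CellulolyticCall",
    "parse_annotation",
    "classify_cellulolytic",
    "score_genome",
    "screen_batch",
]

ENDO_FAMILIES = ("GH5", "GH8")
EXO_FAMILIES = ("GH48", "GH6", "GH7", "GH9", "GH16")
BGLU_FAMILIES = ("GH1", "GH3")
LPMO_FAMILIES = ("AA9", "AA10")

_FAMILY_RE = re.compile(r"^(GH|AA|PL|CE|GT|CBM)\d+")


def normalize_family(family: str) -> str:
    """Collapse a CAZy family label to its base family (``GH5_2`` -> ``GH5``)."""
    fam = family.strip()
    m = _FAMILY_RE.match(fam)
    if not m:
        raise ValueError(f"unrecognized CAZy family label: {family!r}")
    return m.group(0)


@dataclass
class CAZymeProfile:
    """Per-genome copy counts of CAZy families."""

    genome_id: str
    family_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fam, n in self.family_counts.items():
            if n < 0:
                raise ValueError(
                    f"negative copy count for {fam} in genome {self.genome_id}"
                )

    def count(self, families: Iterable[str]) -> int:
        return sum(self.family_counts.get(f, 0) for f in families)


@dataclass
class CellulolyticCall:
    """Candidate call and 0-4 point score for one genome."""

    genome_id: str
    has_endo: bool
    has_exo: bool
    has_bglu: bool
    candidate: bool
    baseline: int
    bonus_lpmo: int
    bonus_endo_redundancy: int
    bonus_exo_redundancy: int
    total_score: int


def parse_annotation(rows: Iterable[Sequence[str]]) -> list[CAZymeProfile]:
    """Aggregate (genome_id, gene_id, family) annotation rows into profiles.

    Subfamily suffixes collapse to the base family; a gene annotated with k
    families contributes one copy to each; duplicated (genome, gene, family)
    rows are counted once. Rows may carry extra columns (e.g. e-value,
    coverage), which are ignored here.
    """
    seen: set[tuple[str, str, str]] = set()
    counts: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for lineno, row in enumerate(rows, start=1):
        if len(row) < 3:
            raise ValueError(f"malformed annotation row at line {lineno}: {row!r}")
        genome, gene, fam_raw = row[0], row[1], row[2]
        if not genome or not gene or not fam_raw:
            raise ValueError(f"malformed annotation row at line {lineno}: {row!r}")
        try:
            fam = normalize_family(fam_raw)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        key = (genome, gene, fam)
        if key in seen:
            continue
        seen.add(key)
        if genome not in counts:
            counts[genome] = {}
            order.append(genome)
        counts[genome][fam] = counts[genome].get(fam, 0) + 1
    return [CAZymeProfile(g, counts[g]) for g in order]


def classify_cellulolytic(profile: CAZymeProfile) -> CellulolyticCall:
    """Candidate call only (score fields zeroed); see :func:`score_genome`."""
    call = score_genome(profile)
    return call


def score_genome(profile: CAZymeProfile,
                 bonus_requires_baseline: bool = True) -> CellulolyticCall:
    """Apply the candidate criteria and the 1-baseline + 3-bonus scoring.

    Redundancy is counted across all families within a functional category
    (GH5=1 plus GH8=1 satisfies endoglucanase redundancy).
    """
    has_endo = profile.count(ENDO_FAMILIES) >= 1
    has_exo = profile.count(EXO_FAMILIES) >= 1
    has_bglu = profile.count(BGLU_FAMILIES) >= 1
    candidate = has_endo and has_exo and has_bglu
    baseline = 1 if candidate else 0
    eligible = candidate or not bonus_requires_baseline
    bonus_lpmo = 1 if eligible and profile.count(LPMO_FAMILIES) >= 1 else 0
    bonus_endo = 1 if eligible and profile.count(ENDO_FAMILIES) >= 2 else 0
    bonus_exo = 1 if eligible and profile.count(EXO_FAMILIES) >= 2 else 0
    return CellulolyticCall(
        genome_id=profile.genome_id,
        has_endo=has_endo,
        has_exo=has_exo,
        has_bglu=has_bglu,
        candidate=candidate,
        baseline=baseline,
        bonus_lpmo=bonus_lpmo,
        bonus_endo_redundancy=bonus_endo,
        bonus_exo_redundancy=bonus_exo,
        total_score=baseline + bonus_lpmo + bonus_endo + bonus_exo,
    )


def screen_batch(profiles: Iterable[CAZymeProfile],
                 bonus_requires_baseline: bool = True) -> pd.DataFrame:
    """Score a batch of genomes; sorted by total_score desc, then genome_id."""
    calls = [score_genome(p, bonus_requires_baseline) for p in profiles]
    df = pd.DataFrame([vars(c) for c in calls])
    if df.empty:
        return pd.DataFrame(
            columns=["genome_id", "has_endo", "has_exo", "has_bglu", "candidate",
                     "baseline", "bonus_lpmo", "bonus_endo_redundancy",
                     "bonus_exo_redundancy", "total_score"]
        )
    return (
        df.sort_values(["total_score", "genome_id"],
                       ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
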