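"""Participant profiles, superuser classification, and cohort summaries.

Two superuser definitions are supported: the strict more-than-N-posts rule
(default N=100) and the top-P-percent-by-post-count rule (default P=1).
Both are kept because the source material uses both; the min-posts rule is
the default since it is the one that can be checked row-by-row against the
shipped participant table.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from ._util import round_half_up

SEX_VALUES = ("F", "M")
IDENTITY_SURVIVOR = "survivor"
IDENTITY_CAREGIVER = "caregiver"


@dataclass(frozen=True)
class UserProfile:
    """One participant row (demographics plus activity counts)."""

    user_id: str
    age_when_posting: Optional[int] = None
    age_at_stroke: Optional[int] = None
    time_since_stroke: Optional[float] = None
    sex: Optional[str] = None
    identity: Optional[str] = None
    times_metaphor_used: int = 0
    total_posts: int = 0
    superuser: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.times_metaphor_used < 0 or self.total_posts < 0:
            raise ValueError("counts must be non-negative")
        if self.total_posts < self.times_metaphor_used:
            raise ValueError(
                f"{self.user_id}: total_posts ({self.total_posts}) < "
                f"times_metaphor_used ({self.times_metaphor_used})"
            )
        if (
            self.age_when_posting is not None
            and self.age_at_stroke is not None
            and self.age_when_posting < self.age_at_stroke
        ):
            raise ValueError(
                f"{self.user_id}: age_when_posting < age_at_stroke"
            )


@dataclass(frozen=True)
class SuperuserRule:
    """Which superuser definition to apply; exactly one mode at a time."""

    mode: str = "min_posts"  # min_posts | top_percent
    min_posts: int = 100
    top_percent: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in {"min_posts", "top_percent"}:
            raise ValueError(f"unknown superuser rule mode {self.mode!r}")

    @classmethod
    def parse(cls, spec: str) -> "SuperuserRule":
        """Parse CLI-style ``min_posts:100`` / ``top_percent:1``."""
        mode, _, value = spec.partition(":")
        mode = mode.strip()
        if mode == "min_posts":
            return cls(mode=mode, min_posts=int(value) if value else 100)
        if mode == "top_percent":
            return cls(mode=mode, top_percent=float(value) if value else 1.0)
        raise ValueError(f"unknown superuser rule {spec!r}")


def classify_superusers(
    post_counts: Mapping[str, int], rule: SuperuserRule
) -> frozenset[str]:
    """Return the set of superusers under the given rule.

    min_posts mode is strict: a user qualifies with count > min_posts.
    top_percent mode takes the ceil(P/100 * n_users) highest counts and
    includes every user tied at the cutoff count.
    """
    if any(c < 0 for c in post_counts.values()):
        raise ValueError("post counts must be non-negative")
    if not post_counts:
        return frozenset()
    if rule.mode == "min_posts":
        return frozenset(u for u, c in post_counts.items() if c > rule.min_posts)
    k = math.ceil(rule.top_percent / 100.0 * len(post_counts))
    if k <= 0:
        return frozenset()
    ranked = sorted(post_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    cutoff = ranked[k - 1][1]
    return frozenset(u for u, c in post_counts.items() if c >= cutoff)


@dataclass
class CohortSummary:
    n_profiles: int
    mean_age_when_posting: Optional[int]
    mean_age_at_stroke: Optional[int]
    mean_age_when_posting_raw: Optional[float]
    mean_age_at_stroke_raw: Optional[float]
    identity_counts: dict[str, int]
    sex_counts: dict[str, int]
    total_metaphor_uses: int
    n_superusers: int
    excluded: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, object]:
        return {
            "n_profiles": self.n_profiles,
            "mean_age_when_posting": self.mean_age_when_posting,
            "mean_age_at_stroke": self.mean_age_at_stroke,
            "mean_age_when_posting_raw": self.mean_age_when_posting_raw,
            "mean_age_at_stroke_raw": self.mean_age_at_stroke_raw,
            "identity_counts": self.identity_counts,
            "sex_counts": self.sex_counts,
            "total_metaphor_uses": self.total_metaphor_uses,
            "n_superusers": self.n_superusers,
            "excluded": self.excluded,
        }

    def to_markdown(self) -> str:
        lines = [
            "| statistic | value |",
            "| --- | --- |",
            f"| profiles | {self.n_profiles} |",
            f"| mean age when posting | {self.mean_age_when_posting} |",
            f"| mean age at stroke | {self.mean_age_at_stroke} |",
            f"| total phrase uses | {self.total_metaphor_uses} |",
            f"| superusers | {self.n_superusers} |",
        ]
        for k, v in sorted(self.identity_counts.items()):
            lines.append(f"| identity: {k} | {v} |")
        for k, v in sorted(self.sex_counts.items()):
            lines.append(f"| sex: {k} | {v} |")
        return "\n".join(lines)


def summarize_cohort(profiles: Iterable[UserProfile]) -> CohortSummary:
    """Arithmetic means (half-up to integer years) over all supplied rows,
    plus identity/sex tallies, total phrase uses and superuser count.

    Rows missing a numeric field are excluded from that mean only, and
    listed in ``excluded``.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("summarize_cohort requires at least one profile")

    def _mean(attr: str) -> tuple[Optional[float], list[str]]:
        vals, skipped = [], []
        for p in profiles:
            v = getattr(p, attr)
            if v is None:
                skipped.append(p.user_id)
            else:
                vals.append(v)
        return (sum(vals) / len(vals) if vals else None), skipped

    raw_posting, skip_posting = _mean("age_when_posting")
    raw_stroke, skip_stroke = _mean("age_at_stroke")
    identity_counts: dict[str, int] = {}
    sex_counts: dict[str, int] = {}
    for p in profiles:
        if p.identity:
            identity_counts[p.identity] = identity_counts.get(p.identity, 0) + 1
        if p.sex:
            sex_counts[p.sex] = sex_counts.get(p.sex, 0) + 1
    excluded = {}
    if skip_posting:
        excluded["age_when_posting"] = skip_posting
    if skip_stroke:
        excluded["age_at_stroke"] = skip_stroke
    return CohortSummary(
        n_profiles=len(profiles),
        mean_age_when_posting=(
            round_half_up(raw_posting) if raw_posting is not None else None
        ),
        mean_age_at_stroke=(
            round_half_up(raw_stroke) if raw_stroke is not None else None
        ),
        mean_age_when_posting_raw=raw_posting,
        mean_age_at_stroke_raw=raw_stroke,
        identity_counts=identity_counts,
        sex_counts=sex_counts,
        total_metaphor_uses=sum(p.times_metaphor_used for p in profiles),
        n_superusers=sum(1 for p in profiles if p.superuser),
        excluded=excluded,
    )


# -- profile I/O -----------------------------------------------------------

_PROFILE_COLUMNS = [
    "user",
    "age_when_posting",
    "age_at_stroke",
    "time_since_stroke",
    "sex",
    "identity",
    "times_metaphor_used",
    "total_posts",
    "superuser",
]


def _opt_int(value: str | None) -> Optional[int]:
    return int(value) if value not in (None, "") else None


def _opt_float(value: str | None) -> Optional[float]:
    return float(value) if value not in (None, "") else None


def read_profiles(path: str | Path) -> list[UserProfile]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            su = (row.get("superuser") or "").strip().lower()
            out.append(
                UserProfile(
                    user_id=row["user"],
                    age_when_posting=_opt_int(row.get("age_when_posting")),
                    age_at_stroke=_opt_int(row.get("age_at_stroke")),
                    time_since_stroke=_opt_float(row.get("time_since_stroke")),
                    sex=row.get("sex") or None,
                    identity=(row.get("identity") or "").lower() or None,
                    times_metaphor_used=int(row.get("times_metaphor_used") or 0),
                    total_posts=int(row.get("total_posts") or 0),
                    superuser=(su in {"yes", "true", "1"}) if su else None,
                )
            )
    return out


def write_profiles(profiles: Iterable[UserProfile], path: str | Path) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_PROFILE_COLUMNS)
        for p in profiles:
            writer.writerow(
                [
                    p.user_id,
                    p.age_when_posting if p.age_when_posting is not None else "",
                    p.age_at_stroke if p.age_at_stroke is not None else "",
                    p.time_since_stroke if p.time_since_stroke is not None else "",
                    p.sex or "",
                    p.identity or "",
                    p.times_metaphor_used,
                    p.total_posts,
                    "" if p.superuser is None else ("yes" if p.superuser else "no"),
                ]
            )
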