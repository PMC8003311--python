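"""Nine-point quiet-area surveys and the composite urban quietness index.

A candidate quiet area is sampled at eight points on its perimeter
(``edge1``..``edge8``) and one at its core. Per-point ACI and NDSI values
are combined into:

* ``CB``  — complexity balance: mean edge ACI / core ACI. Close to 1 means
  spatially balanced acoustic complexity; below 1 suggests the edges are
  masked by noise; above 1, a complexity-poor core.
* ``RG_ACI`` — the range (max - min) of ACI over all nine points.
* ``AD``  — anthropogenic disturbance: the sign of the mean NDSI over the
  nine points (-1 when human-generated sound dominates, +1 when biological
  sound does, 0 at exact balance).
* ``CUQI = AD x (RG_ACI x CB)`` — positive and high for a balanced, complex,
  biophony-dominated acoustic environment; negative when anthropogenic and
  probably masking sounds prevail.

Because raw ACI totals scale with frame count, all nine recordings must
share duration and analysis parameters; this module enforces both.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from quietscape.audio_io import AudioClip, condition, read_wav, truncate_to
from quietscape.indices import AnalysisParams, compute_all

__all__ = [
    "ROLES",
    "EDGE_ROLES",
    "SamplingPoint",
    "AreaSurvey",
    "AreaScore",
    "SilentCoreError",
    "complexity_balance",
    "aci_range",
    "anthropogenic_disturbance",
    "cuqi",
    "rank_areas",
    "survey_from_clips",
    "surveys_from_manifest",
    "scores_to_frame",
]

EDGE_ROLES: tuple[str, ...] = tuple(f"edge{i}" for i in range(1, 9))
ROLES: tuple[str, ...] = EDGE_ROLES + ("core",)


class SilentCoreError(ValueError):
    """Core recording has zero acoustic complexity: CB is undefined.

    A zero-ACI core signals a broken measurement (dead microphone, clipped
    file), not infinite quietness, so it is an error rather than CUQI = inf.
    """


@dataclasses.dataclass(frozen=True)
class SamplingPoint:
    """One surveyed location: its grid role and its two index values."""

    role: str
    clip_ref: str
    aci: float
    ndsi: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.aci < 0:
            raise ValueError(f"ACI must be >= 0, got {self.aci}")
        if not -1.0 <= self.ndsi <= 1.0:
            raise ValueError(f"NDSI must lie in [-1, 1], got {self.ndsi}")


@dataclasses.dataclass(frozen=True)
class AreaSurvey:
    """The complete nine-point sampling grid of one candidate quiet area."""

    area_name: str
    points: tuple[SamplingPoint, ...]
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = sorted(p.role for p in self.points)
        if roles != sorted(ROLES):
            missing = set(ROLES) - set(roles)
            dupes = {r for r in roles if roles.count(r) > 1}
            detail = []
            if missing:
                detail.append(f"missing role(s) {sorted(missing)}")
            if dupes:
                detail.append(f"duplicate role(s) {sorted(dupes)}")
            raise ValueError(f"survey {self.area_name!r}: {'; '.join(detail) or 'bad roles'}")

    def point(self, role: str) -> SamplingPoint:
        return next(p for p in self.points if p.role == role)

    @property
    def edge_acis(self) -> list[float]:
        return [self.point(r).aci for r in EDGE_ROLES]

    @property
    def core_aci(self) -> float:
        return self.point("core").aci

    @property
    def all_acis(self) -> list[float]:
        return [p.aci for p in self.points]

    @property
    def mean_ndsi(self) -> float:
        return sum(p.ndsi for p in self.points) / len(self.points)


@dataclasses.dataclass(frozen=True)
class AreaScore:
    """CUQI and its three constituents for one area; cuqi is recomputable
    bit-for-bit as ad * (rg_aci * cb)."""

    area_name: str
    cb: float
    rg_aci: float
    ad: int
    cuqi: float

    def __post_init__(self) -> None:
        if self.ad not in (-1, 0, 1):
            raise ValueError(f"AD must be -1, 0 or +1, got {self.ad}")
        if self.cuqi != self.ad * (self.rg_aci * self.cb):
            raise ValueError("stored cuqi does not equal ad * (rg_aci * cb)")


def complexity_balance(survey: AreaSurvey) -> float:
    """CB = mean(edge ACIs) / core ACI."""
    core = survey.core_aci
    if core == 0.0:
        raise SilentCoreError(
            f"survey {survey.area_name!r}: core ACI is 0, complexity balance undefined"
        )
    return sum(survey.edge_acis) / len(survey.edge_acis) / core


def aci_range(survey: AreaSurvey) -> float:
    """RG_ACI = max - min of ACI over all nine points, core included."""
    acis = survey.all_acis
    return max(acis) - min(acis)


def anthropogenic_disturbance(survey: AreaSurvey) -> int:
    """AD = sign of the nine-point mean NDSI (0 at exact balance)."""
    m = survey.mean_ndsi
    if m > 0:
        return 1
    if m < 0:
        return -1
    return 0


def cuqi(survey: AreaSurvey) -> AreaScore:
    """Composite urban quietness index: CUQI = AD x (RG_ACI x CB)."""
    cb = complexity_balance(survey)
    rg = aci_range(survey)
    ad = anthropogenic_disturbance(survey)
    return AreaScore(area_name=survey.area_name, cb=cb, rg_aci=rg, ad=ad, cuqi=ad * (rg * cb))


def rank_areas(scores: Iterable[AreaScore]) -> list[tuple[int, AreaScore]]:
    """Order areas by descending CUQI, ties broken by area name.

    Returns 1-based ``(rank, score)`` pairs; deterministic for any input
    order. Duplicate area names are a validation error.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("need at least one AreaScore to rank")
    names = [s.area_name for s in scores]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate area name(s): {dupes}")
    ordered = sorted(scores, key=lambda s: (-s.cuqi, s.area_name))
    return [(i + 1, s) for i, s in enumerate(ordered)]


def survey_from_clips(
    area_name: str,
    clips: Mapping[str, AudioClip],
    params: AnalysisParams | None = None,
    clip_refs: Mapping[str, str] | None = None,
) -> AreaSurvey:
    """Build an AreaSurvey by analysing nine role-keyed clips.

    Clips are conditioned to mono and truncated to the shortest duration in
    the set before index extraction, so raw ACI totals stay comparable.
    """
    missing = set(ROLES) - set(clips)
    if missing:
        raise ValueError(f"survey {area_name!r}: missing role(s) {sorted(missing)}")
    p = params or AnalysisParams()
    conditioned = {role: condition(clips[role]) for role in ROLES}
    rates = {c.sample_rate for c in conditioned.values()}
    if len(rates) > 1:
        raise ValueError(f"survey {area_name!r}: clips mix sample rates {sorted(rates)}")
    n_min = min(c.n_samples for c in conditioned.values())
    points = []
    for role in ROLES:
        clip = truncate_to(conditioned[role], n_min)
        res = compute_all(clip, p)
        ref = clip_refs[role] if clip_refs else role
        points.append(
            SamplingPoint(role=role, clip_ref=ref, aci=res["ACI"].value, ndsi=res["NDSI"].value)
        )
    return AreaSurvey(area_name=area_name, points=tuple(points), params=p.as_dict())


def surveys_from_manifest(
    manifest_path: str | Path,
    params: AnalysisParams | None = None,
) -> list[AreaSurvey]:
    """Load surveys from a manifest CSV with columns area_name, role, wav_path.

    Relative wav paths are resolved against the manifest's directory. Each
    area must supply all nine roles exactly once.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"area_name", "role", "wav_path"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"manifest {manifest_path} lacks column(s) {sorted(required - set(df.columns))}"
        )
    surveys = []
    for area_name, group in df.groupby("area_name", sort=True):
        clips, refs = {}, {}
        for row in group.itertuples():
            role = str(row.role)
            if role not in ROLES:
                raise ValueError(f"area {area_name!r}: unknown role {role!r}")
            if role in clips:
                raise ValueError(f"area {area_name!r}: duplicate role {role!r}")
            wav = Path(row.wav_path)
            if not wav.is_absolute():
                wav = manifest_path.parent / wav
            clips[role] = read_wav(wav)
            refs[role] = str(row.wav_path)
        missing = set(ROLES) - set(clips)
        if missing:
            raise ValueError(f"area {area_name!r}: missing role(s) {sorted(missing)}")
        surveys.append(survey_from_clips(str(area_name), clips, params, clip_refs=refs))
    return surveys


def scores_to_frame(ranked: list[tuple[int, AreaScore]]) -> pd.DataFrame:
    """Tabulate ranked scores (one row per area)."""
    return pd.DataFrame(
        [
            {
                "rank": rank,
                "area_name": s.area_name,
                "cb": s.cb,
                "rg_aci": s.rg_aci,
                "ad": s.ad,
                "cuqi": s.cuqi,
            }
            for rank, s in ranked
        ]
    )
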