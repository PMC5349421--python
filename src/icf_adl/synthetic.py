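"""Seeded synthetic cohorts of HC / MCI / AD participants with ADL interviews.

The generator emulates the structure of the validation study: three groups
(healthy comparison n=79, mild cognitive impairment n=73, Alzheimer disease
n=71) with demographic covariates, conventional-scale comparator totals
(Katz, Lawton, MMSE) and item-level ADL assessments whose group-level index
distributions track the published construct-validity means.

Model.  Given group and domain, item qualifier scores are drawn
independently per item from a categorical distribution over {0..4}; the
default distributions are Binomial(4, q) with q = mean_DI/100 so that the
expected DI matches the calibration target for that group and domain.
Each limited item draws a cognitive cause with probability ``p_cognitive``
and, independently, a physical cause with probability ``p_physical`` (their
product is the dual-cause overlap); an "other" cause (intrapersonal, social
or environmental, uniform) is added with probability ``p_other``, and
always when neither main cause fired.  Under this model
E[CDI] = E[DI] * p_cognitive exactly, which is how the defaults are
back-fitted from the published index means.  The healthy group's b-ADL
cognitive-cause probability is 0, so its b-ADL-CDI is identically zero.

Item scores are independent across items given the group; no within-person
severity correlation is imposed, so within-group index SDs are smaller
than in real data.  This is a deliberate simplification (see the methods
note) — the cohorts are for end-to-end testing and calibration ordering,
not for reproducing sampling variability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import yaml

from .instrument import (
    Assessment,
    Cause,
    Domain,
    ItemResponse,
    ReportMode,
    load_catalog,
)
from .psychometrics import Participant

_OTHER_CAUSES = (Cause.INTRAPERSONAL, Cause.SOCIAL, Cause.ENVIRONMENTAL)


def _binomial_score_probs(mean_di_percent: float) -> list[float]:
    """Categorical score distribution with E[score] = 4 * mean_DI / 100."""
    from scipy.stats import binom
    q = np.clip(mean_di_percent / 100.0, 0.0, 1.0)
    return [float(binom.pmf(k, 4, q)) for k in range(5)]


@dataclass
class CovariateSpec:
    """Normal covariate clipped to an observed range (rounded if integer)."""

    mean: float
    sd: float
    low: float
    high: float
    integer: bool = False

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.normal(self.mean, self.sd, size=n)
        x = np.clip(x, self.low, self.high)
        return np.round(x).astype(int) if self.integer else np.round(x, 1)


@dataclass
class DomainProfile:
    """Per-domain generative settings for one group."""

    score_probs: list[float]
    p_cognitive: float
    p_physical: float
    p_other: float = 0.15

    def validate(self) -> None:
        p = np.asarray(self.score_probs, dtype=float)
        if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("score_probs must be 5 non-negative values summing to 1")
        for name in ("p_cognitive", "p_physical", "p_other"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GroupSpec:
    n: int
    female_fraction: float
    age: CovariateSpec
    education: CovariateSpec
    medications: CovariateSpec
    comorbidities: CovariateSpec
    mmse: CovariateSpec
    katz: CovariateSpec
    lawton: CovariateSpec
    basic: DomainProfile
    instrumental: DomainProfile

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        self.basic.validate()
        self.instrumental.validate()


@dataclass
class CohortConfig:
    """Full generator configuration; :meth:`default` reproduces the study design."""

    groups: dict[str, GroupSpec]
    i_adl_relevance_prob: float = 8.0 / 9.0
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("no groups configured")
        if not 0.0 < self.i_adl_relevance_prob <= 1.0:
            raise ValueError("i_adl_relevance_prob must lie in (0, 1]")
        for spec in self.groups.values():
            spec.validate()

    # Defaults: group sizes and covariates from the published participant
    # characteristics; index calibration targets (group-mean DI / CDI / PDI
    # per domain) from the published construct-validity table, turned into
    # score distributions and cause probabilities as described above.
    @classmethod
    def default(cls, seed: int = 0) -> "CohortConfig":
        def profile(di, cdi, pdi):
            return DomainProfile(
                score_probs=_binomial_score_probs(di),
                p_cognitive=0.0 if di == 0 else min(cdi / di, 1.0),
                p_physical=0.0 if di == 0 else min(pdi / di, 1.0),
            )

        groups = {
            "HC": GroupSpec(
                n=79, female_fraction=0.570,
                age=CovariateSpec(76.6, 6.6, 65, 91),
                education=CovariateSpec(13.3, 3.1, 6, 18, integer=True),
                medications=CovariateSpec(4.0, 2.5, 0, 10, integer=True),
                comorbidities=CovariateSpec(3.3, 2.0, 0, 9, integer=True),
                mmse=CovariateSpec(28.6, 1.2, 26, 30, integer=True),
                katz=CovariateSpec(6.2, 0.6, 6, 10, integer=True),
                lawton=CovariateSpec(24.4, 2.8, 15, 27, integer=True),
                basic=profile(2.0, 0.0, 1.9),
                instrumental=profile(11.2, 1.3, 6.1),
            ),
            "MCI": GroupSpec(
                n=73, female_fraction=0.575,
                age=CovariateSpec(80.8, 5.0, 71, 91),
                education=CovariateSpec(11.4, 2.8, 6, 18, integer=True),
                medications=CovariateSpec(5.9, 2.9, 1, 12, integer=True),
                comorbidities=CovariateSpec(5.0, 2.5, 1, 12, integer=True),
                mmse=CovariateSpec(26.1, 2.0, 22, 30, integer=True),
                katz=CovariateSpec(7.4, 1.8, 6, 13, integer=True),
                lawton=CovariateSpec(20.2, 4.2, 10, 27, integer=True),
                basic=profile(10.9, 2.1, 9.1),
                instrumental=profile(36.8, 19.3, 17.2),
            ),
            "AD": GroupSpec(
                n=71, female_fraction=0.676,
                age=CovariateSpec(81.9, 5.4, 71, 93),
                education=CovariateSpec(10.9, 2.7, 6, 18, integer=True),
                medications=CovariateSpec(6.4, 2.9, 1, 12, integer=True),
                comorbidities=CovariateSpec(5.8, 2.6, 1, 12, integer=True),
                mmse=CovariateSpec(21.7, 2.8, 16, 28, integer=True),
                katz=CovariateSpec(8.1, 2.6, 6, 20, integer=True),
                lawton=CovariateSpec(16.9, 4.0, 9, 26, integer=True),
                basic=profile(17.5, 6.3, 12.6),
                instrumental=profile(55.6, 43.2, 20.7),
            ),
        }
        return cls(groups=groups, seed=seed)

    # -- YAML round-trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        groups = {}
        for name, g in raw["groups"].items():
            kwargs = {"n": g["n"], "female_fraction": g["female_fraction"]}
            for cov in ("age", "education", "medications", "comorbidities",
                        "mmse", "katz", "lawton"):
                kwargs[cov] = CovariateSpec(**g[cov])
            for dom in ("basic", "instrumental"):
                kwargs[dom] = DomainProfile(**g[dom])
            groups[name] = GroupSpec(**kwargs)
        return cls(groups=groups,
                   i_adl_relevance_prob=raw.get("i_adl_relevance_prob", 8.0 / 9.0),
                   seed=raw.get("seed", 0))


def _draw_causes(rng: np.random.Generator, profile: DomainProfile) -> frozenset:
    causes = set()
    if rng.random() < profile.p_cognitive:
        causes.add(Cause.COGNITIVE)
    if rng.random() < profile.p_physical:
        causes.add(Cause.PHYSICAL)
    if rng.random() < profile.p_other or not causes:
        causes.add(_OTHER_CAUSES[rng.integers(len(_OTHER_CAUSES))])
    return frozenset(causes)


def _draw_assessment(rng, pid, group, domain, profile, relevance_prob,
                     report_mode) -> Assessment:
    catalog = load_catalog(domain)
    if domain is Domain.BASIC:
        relevant = np.ones(len(catalog), dtype=bool)
    else:
        relevant = rng.random(len(catalog)) < relevance_prob
        if not relevant.any():
            relevant[rng.integers(len(catalog))] = True  # enforce TNA >= 1
    scores = rng.choice(5, size=len(catalog), p=profile.score_probs)
    responses = []
    for i, item in enumerate(catalog):
        if not relevant[i]:
            responses.append(ItemResponse(item.item_id, relevant=False))
            continue
        s = int(scores[i])
        causes = _draw_causes(rng, profile) if s >= 1 else frozenset()
        responses.append(ItemResponse(item.item_id, True, s, causes))
    return Assessment(pid, domain, tuple(responses), report_mode)


def generate_cohort(config: Optional[CohortConfig] = None,
                    seed: Optional[int] = None,
                    ) -> tuple[list[Participant], list[Assessment]]:
    """Generate a full synthetic cohort: participants plus both-domain interviews.

    Reproducible given the seed (``seed`` overrides ``config.seed``).  Every
    generated assessment passes strict validation.  Healthy participants use
    self-report; MCI and AD use proxy report.
    """
    config = CohortConfig.default() if config is None else config
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    participants: list[Participant] = []
    assessments: list[Assessment] = []
    counter = 0
    for group, spec in config.groups.items():
        cov = {name: getattr(spec, name).draw(rng, spec.n)
               for name in ("age", "education", "medications", "comorbidities",
                            "mmse", "katz", "lawton")}
        female = rng.random(spec.n) < spec.female_fraction
        mode = ReportMode.SELF if group == "HC" else ReportMode.PROXY
        for i in range(spec.n):
            counter += 1
            pid = f"P{counter:04d}"
            participants.append(Participant(
                participant_id=pid, group=group,
                age=float(cov["age"][i]), education=float(cov["education"][i]),
                gender="female" if female[i] else "male",
                n_medications=int(cov["medications"][i]),
                n_comorbidities=int(cov["comorbidities"][i]),
                mmse=float(cov["mmse"][i]),
                katz_total=float(cov["katz"][i]),
                lawton_total=float(cov["lawton"][i]),
            ))
            assessments.append(_draw_assessment(
                rng, pid, group, Domain.BASIC, spec.basic, 1.0, mode))
            assessments.append(_draw_assessment(
                rng, pid, group, Domain.INSTRUMENTAL, spec.instrumental,
                config.i_adl_relevance_prob, mode))
    return participants, assessments


def generate_rater_pair(assessments: Iterable[Assessment],
                        disagreement_rate: float,
                        seed: int = 0,
                        ) -> tuple[list[Assessment], list[Assessment]]:
    """Simulate a second independent rater observing the same interviews.

    With probability ``disagreement_rate`` per relevant item the second
    rater's qualifier score moves one point up or down (clipped to 0-4).  A
    score perturbed to 0 loses its causes; a score perturbed from 0 to 1
    gains one randomly drawn cause so the record stays strictly valid.
    Deterministic given the seed.
    """
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rater_a, rater_b = [], []
    all_causes = tuple(Cause)
    for a in assessments:
        rater_a.append(a)
        responses = []
        for r in a.responses:
            if r.relevant and r.score is not None and rng.random() < disagreement_rate:
                step = 1 if rng.random() < 0.5 else -1
                new = int(np.clip(r.score + step, 0, 4))
                if new == r.score:  # clipped at a boundary: go the other way
                    new = int(np.clip(r.score - step, 0, 4))
                if new == 0:
                    causes = frozenset()
                elif r.causes:
                    causes = r.causes
                else:
                    causes = frozenset({all_causes[rng.integers(len(all_causes))]})
                responses.append(dataclasses.replace(r, score=new, causes=causes))
            else:
                responses.append(r)
        rater_b.append(Assessment(a.participant_id, a.domain,
                                  tuple(responses), a.report_mode))
    return rater_a, rater_b
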