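"""Combinatorial model of cohesin-ring circularization and DNA entrapment.

Cohesin is a tripartite Smc1/Smc3/kleisin ring.  When cysteine pairs are
engineered at all three subunit interfaces ("6C" cohesin), a thiol-specific
crosslinker can covalently circularize the ring; a "5C" variant lacking one
cysteine pair can never fully circularize.  In the minichromosome IP assay,
covalent circularization converts topological entrapment into SDS-resistant
species: a catenated monomer (CM, one DNA inside one ring) or a catenated
dimer (CD, two sister DNAs co-entrapped by a cohesive unit).

The model asks how the detectable CD fraction scales with the number ``k`` of
kleisin-containing rings required per cohesive unit.  ``k = 1`` is the ring
model (a single ring holds both sisters); ``k >= 2`` is the handcuff/oligomer
model.  Cells co-expressing circularizable (6C) and non-circularizable (5C)
copies dilute the pool of rings that can be trapped covalently: with one 6C
copy among four total, each extra ring a cohesive unit needs multiplies its
detectable fraction by 1/4, so the CD/CM ratio discriminates k.

Partner rings in a unit are drawn uniformly, with replacement, from the
expressed copy pool, and interface crosslinking events are independent; a CD
is detectable only if *every* member ring is fully circularized, and the IP
requires the unit to contain at least one epitope-tagged ring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "INTERFACES",
    "CohesinCopy",
    "StoichiometryModel",
    "LaneQuantification",
    "ReplicateSummary",
    "ClassificationResult",
    "six_c",
    "five_c",
    "standard_tetraploid_designs",
    "circularization_fraction",
    "expected_species_fractions",
    "ratio_of_ratios",
    "quantify_lane",
    "replicate_stats",
    "ratio_of_ratios_from_lanes",
    "classify_stoichiometry",
]

#: The three ring-subunit interfaces that can carry a cysteine pair.
INTERFACES = ("hinge", "smc3_kleisin", "kleisin_smc1")


@dataclass(frozen=True)
class CohesinCopy:
    """One expressed cohesin copy.

    ``circularizable`` is the subset of interfaces carrying a cysteine pair;
    a copy can fully circularize only when all three are present (6C).
    ``tagged`` marks the copy whose kleisin carries the IP epitope.
    """

    circularizable: frozenset[str]
    tagged: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.circularizable) - set(INTERFACES)
        if unknown:
            raise ValueError(f"unknown interfaces: {sorted(unknown)}")

    @property
    def is_6c(self) -> bool:
        return set(self.circularizable) == set(INTERFACES)


def six_c(tagged: bool = False) -> CohesinCopy:
    """A fully circularizable (6C) copy."""
    return CohesinCopy(frozenset(INTERFACES), tagged=tagged)


def five_c(missing: str = "kleisin_smc1", tagged: bool = False) -> CohesinCopy:
    """A 5C copy lacking the cysteine pair at one interface.

    The default missing interface is kleisin–Smc1 (the 5C strains lack the
    kleisin C-terminal cysteine); the model's predictions do not depend on
    which interface is absent.
    """
    if missing not in INTERFACES:
        raise ValueError(f"unknown interface {missing!r}")
    return CohesinCopy(frozenset(i for i in INTERFACES if i != missing), tagged=tagged)


@dataclass
class StoichiometryModel:
    """Copy composition and crosslink efficiencies for an entrapment assay.

    Parameters
    ----------
    efficiencies
        Per-interface crosslink probability ``e_i`` in [0, 1].
    copies
        The expressed copy pool (e.g. 4 copies in a tetraploid); at least
        one copy must be tagged.
    k
        Number of kleisin-containing rings per cohesive unit (1 = ring
        model, >= 2 = handcuff/oligomer).
    p_cm
        Fraction of tagged complexes entrapping a single DNA.
    p_cd
        Fraction of cohesive units sitting on replicated minichromosomes.
    """

    efficiencies: Mapping[str, float]
    copies: Sequence[CohesinCopy]
    k: int = 1
    p_cm: float = 1.0
    p_cd: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.efficiencies) != set(INTERFACES):
            raise ValueError(
                f"efficiencies must be given for exactly {INTERFACES}, "
                f"got {sorted(self.efficiencies)}"
            )
        for name, e in self.efficiencies.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"efficiency {name}={e} outside [0, 1]")
        if not self.copies:
            raise ValueError("copy pool is empty")
        if not any(c.tagged for c in self.copies):
            raise ValueError("at least one copy must be tagged")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        for name, p in (("p_cm", self.p_cm), ("p_cd", self.p_cd)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


def standard_tetraploid_designs(
    k: int,
    e: float | Mapping[str, float] = 0.6,
    p_cm: float = 0.5,
    p_cd: float = 0.5,
) -> tuple[StoichiometryModel, StoichiometryModel]:
    """The matched tetraploid pair used to discriminate ring vs handcuff.

    Returns ``(control, test)``: a 4x6C tetraploid with one tagged copy, and
    a 1x6C(tagged) + 3x5C tetraploid, sharing efficiencies, ``k`` and the
    detection fractions.
    """
    if isinstance(e, Mapping):
        eff = dict(e)
    else:
        eff = {i: float(e) for i in INTERFACES}
    control = StoichiometryModel(
        eff, [six_c(tagged=True), six_c(), six_c(), six_c()], k=k, p_cm=p_cm, p_cd=p_cd
    )
    test = StoichiometryModel(
        eff, [six_c(tagged=True), five_c(), five_c(), five_c()], k=k, p_cm=p_cm, p_cd=p_cd
    )
    return control, test


def circularization_fraction(model: StoichiometryModel, copy_index: int) -> float:
    """Probability that one copy is covalently circularized by crosslinking.

    Full circularization needs a crosslink at every interface, so the
    probability is the product of the per-interface efficiencies for a 6C
    copy and exactly 0 for any copy missing an interface cysteine pair.
    """
    if not 0 <= copy_index < len(model.copies):
        raise IndexError(
            f"copy_index {copy_index} out of range for {len(model.copies)} copies"
        )
    copy = model.copies[copy_index]
    if not copy.is_6c:
        return 0.0
    return math.prod(model.efficiencies[i] for i in copy.circularizable)


def expected_species_fractions(model: StoichiometryModel) -> dict[str, float]:
    """Expected detectable CM and CD fractions for a copy composition.

    ``CM_detectable`` is the chance that a tagged, single-DNA-entrapping
    complex survives SDS, i.e. that the tagged ring is fully circularized.
    ``CD_detectable`` additionally requires the ``k - 1`` partner rings of
    the cohesive unit (drawn uniformly with replacement from the expressed
    pool) to all be circularized, giving a factor ``m**(k-1)`` where ``m``
    is the pool-mean circularization fraction.
    """
    fracs = [circularization_fraction(model, i) for i in range(len(model.copies))]
    tagged = [f for f, c in zip(fracs, model.copies) if c.tagged]
    c_tag = sum(tagged) / len(tagged)
    m = sum(fracs) / len(fracs)
    return {
        "CM_detectable": model.p_cm * c_tag,
        "CD_detectable": model.p_cd * c_tag * m ** (model.k - 1),
    }


def ratio_of_ratios(
    design_control: StoichiometryModel, design_test: StoichiometryModel
) -> float:
    """(CD/CM of the control design) divided by (CD/CM of the test design).

    Under the ring model (k=1) this is exactly 1 regardless of copy
    composition or efficiencies; for the matched tetraploid pair it equals
    ``4**(k-1)``.
    """
    num = expected_species_fractions(design_control)
    den = expected_species_fractions(design_test)
    for label, fr in (("control", num), ("test", den)):
        if fr["CM_detectable"] == 0:
            raise ValueError(f"ratio undefined: CM_detectable is zero in {label} design")
    if den["CD_detectable"] == 0:
        raise ValueError("ratio undefined: CD_detectable is zero in test design")
    return (num["CD_detectable"] / num["CM_detectable"]) / (
        den["CD_detectable"] / den["CM_detectable"]
    )


# ---------------------------------------------------------------------------
# Gel-lane quantification


@dataclass
class LaneQuantification:
    """Band intensities of one gel lane with percent-of-lane quantification."""

    bands: dict[str, float]
    percent: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        for label, v in self.bands.items():
            if v < 0:
                raise ValueError(f"negative intensity for band {label!r}")
        total = sum(self.bands.values())
        if total <= 0:
            raise ValueError("empty lane: total intensity is zero")
        self.percent = {b: 100.0 * v / total for b, v in self.bands.items()}


def quantify_lane(bands: Mapping[str, float]) -> LaneQuantification:
    """Express each band as a percentage of the lane's total intensity."""
    return LaneQuantification(dict(bands))


@dataclass
class ReplicateSummary:
    """Per-band mean and sample SD (n-1) of percent values across replicates."""

    mean: dict[str, float]
    sd: dict[str, float | None]
    n: int


def replicate_stats(lanes: Sequence[LaneQuantification]) -> ReplicateSummary:
    """Mean and sample standard deviation of band percentages.

    With a single lane the SD is undefined and reported as ``None``.
    Raises if the lanes do not share an identical band set.
    """
    if not lanes:
        raise ValueError("no lanes given")
    labels = list(lanes[0].percent)
    for lane in lanes[1:]:
        if set(lane.percent) != set(labels):
            extra = sorted(set(lane.percent) ^ set(labels))
            raise ValueError(f"mismatched band labels across lanes: {extra}")
    n = len(lanes)
    mean: dict[str, float] = {}
    sd: dict[str, float | None] = {}
    for b in labels:
        vals = [lane.percent[b] for lane in lanes]
        mu = sum(vals) / n
        mean[b] = mu
        if n == 1:
            sd[b] = None
        else:
            sd[b] = math.sqrt(sum((v - mu) ** 2 for v in vals) / (n - 1))
    return ReplicateSummary(mean=mean, sd=sd, n=n)


def ratio_of_ratios_from_lanes(
    control_lanes: Sequence[LaneQuantification],
    test_lanes: Sequence[LaneQuantification],
    cd_band: str = "CD",
    cm_band: str = "CM",
) -> tuple[float, float]:
    """Observed CD/CM ratio-of-ratios from replicate lanes, with an SD.

    The per-design CD/CM is the mean over replicate lanes of each lane's
    CD/CM; the returned SD propagates the standard errors of the two design
    means into the ratio (first-order delta method).
    """

    def _mean_sem(lanes: Sequence[LaneQuantification]) -> tuple[float, float]:
        ratios = [lane.bands[cd_band] / lane.bands[cm_band] for lane in lanes]
        n = len(ratios)
        mu = sum(ratios) / n
        if n > 1:
            var = sum((r - mu) ** 2 for r in ratios) / (n - 1)
            sem = math.sqrt(var / n)
        else:
            sem = 0.0
        return mu, sem

    mu_c, sem_c = _mean_sem(control_lanes)
    mu_t, sem_t = _mean_sem(test_lanes)
    if mu_t == 0:
        raise ValueError("ratio undefined: test design CD/CM mean is zero")
    ratio = mu_c / mu_t
    sd = ratio * math.sqrt((sem_c / mu_c) ** 2 + (sem_t / mu_t) ** 2)
    return ratio, sd


@dataclass
class ClassificationResult:
    best_k: int
    z_per_k: dict[int, float]
    tie: bool


def classify_stoichiometry(
    observed_ratio_of_ratios: float,
    observed_sd: float,
    candidate_k: Sequence[int],
    designs: tuple[StoichiometryModel, StoichiometryModel] | None = None,
) -> ClassificationResult:
    """Pick the ring count k whose predicted ratio-of-ratios best fits.

    For each candidate k, ``z = |observed - predicted(k)| / observed_sd``
    where the prediction comes from :func:`ratio_of_ratios` on ``designs``
    (default: the standard matched tetraploid pair, whose prediction
    ``4**(k-1)`` is independent of the crosslink efficiencies).  Ties are
    broken toward smaller k (parsimony) and reported.
    """
    if not candidate_k:
        raise ValueError("candidate_k is empty")
    if observed_sd <= 0:
        raise ValueError("observed_sd must be positive")
    z_per_k: dict[int, float] = {}
    for k in candidate_k:
        if designs is None:
            control, test = standard_tetraploid_designs(k=k)
        else:
            control, test = designs
            control = StoichiometryModel(
                control.efficiencies, control.copies, k=k,
                p_cm=control.p_cm, p_cd=control.p_cd,
            )
            test = StoichiometryModel(
                test.efficiencies, test.copies, k=k,
                p_cm=test.p_cm, p_cd=test.p_cd,
            )
        pred = ratio_of_ratios(control, test)
        z_per_k[k] = abs(observed_ratio_of_ratios - pred) / observed_sd
    best_z = min(z_per_k.values())
    tied = sorted(k for k, z in z_per_k.items() if z == best_z)
    return ClassificationResult(best_k=tied[0], z_per_k=z_per_k, tie=len(tied) > 1)
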