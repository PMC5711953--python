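"""Synthetic marker generator for ascertainment, ILS and introgression models.

The scaffold is a rooted four-taxon tree with a reference taxon R, its
candidate sisters B and C, and an outgroup O.  Markers arise on branches as
Poisson counts (a fixed-count mode exists for exact-expectation tests):

* markers on the internal branch joining the true sister pair resolve to the
  species-tree pattern with probability ``1 - (2/3) exp(-T)`` and to each of
  the two discordant pair patterns with probability ``(1/3) exp(-T)``, the
  standard three-lineage coalescent hemiplasy probabilities for an internal
  branch of T coalescent units;
* an introgression event donates a fraction ``gamma`` of the donor lineage's
  pre-event insertions (``beta`` expected) to the recipient; ``alpha``
  expected insertions postdate the event and stay private.  Expected shared
  markers: ``beta * gamma``; expected donor-exclusive: ``alpha + beta * (1 -
  gamma)``;
* the single-reference ascertainment filter then drops every marker absent in
  the reference taxon.

For insertion-ratio calibration the reference lineage must be an internal
branch (a marker private to one leaf is an uninformative autapomorphy), so
``split_reference`` replaces R by a cherry (R1, R2) and the pre/post-event
donor branches become the two successive reference-path branches the test
reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import bias_tests as bt
from .counts import InsertionCount, RatioCount
from .errors import InvalidArgumentError, SpecError
from .matrix import MarkerMatrix, PRESENT, ABSENT
from .polarity import (
    NodeSpec,
    SpeciesTree,
    TrifurcationSpec,
    polarize_all,
    count_trifurcation,
    ratio_count_for_clade,
)

log = logging.getLogger("blindtree.simulate")

PAIRS = ("RB", "RC", "BC")


@dataclass(frozen=True)
class IntrogressionScenario:
    """Gene flow between non-sister lineages.

    ``alpha``/``beta``: expected donor-stem insertions after/before the
    event; ``gamma``: genome fraction shared and retained; ``direction``:
    (donor, recipient) taxon labels.
    """

    alpha: float
    beta: float
    gamma: float
    direction: tuple = ("R", "B")

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise SpecError("alpha and beta must be >= 0")
        if not (0 < self.gamma < 1):
            raise SpecError("gamma must lie strictly in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation scenario; a fixed seed gives byte-identical output.

    ``species_pair`` names the true sister pair ("BC" puts the reference
    outside it — the blind tree is true).  ``intensity`` maps branch names
    ("internal", "R", "B", "C", "stem") to expected insertion counts;
    ``rate_multipliers`` scales them per branch.  ``internal_branch_length``
    is T in coalescent units.
    """

    species_pair: str = "RB"
    internal_branch_length: float = 1.0
    intensity: dict = field(default_factory=lambda: {"internal": 10.0})
    rate_multipliers: dict = field(default_factory=dict)
    introgression: IntrogressionScenario | None = None
    reference_taxon: str = "R"
    seed: int | None = None
    fixed_counts: bool = False
    split_reference: bool = False
    n_loci: int | None = None  # informational cap, not usually needed

    def __post_init__(self):
        if self.species_pair not in PAIRS:
            raise SpecError(f"species_pair must be one of {PAIRS}")
        if self.internal_branch_length <= 0:
            raise SpecError("internal branch length T must be > 0")
        if any(v < 0 for v in self.intensity.values()):
            raise SpecError("intensities must be >= 0")
        if any(v <= 0 for v in self.rate_multipliers.values()):
            raise SpecError("rate multipliers must be > 0")


def _leaf_sets(config):
    """Map pattern names to taxon sets, honoring split_reference."""
    r = ("R1", "R2") if config.split_reference else ("R",)
    return {
        "R": frozenset(r),
        "B": frozenset({"B"}),
        "C": frozenset({"C"}),
        "RB": frozenset(r) | {"B"},
        "RC": frozenset(r) | {"C"},
        "BC": frozenset({"B", "C"}),
        "RBC": frozenset(r) | {"B", "C"},
    }


def scaffold_newick(config: SimulationConfig) -> str:
    """Rooted Newick of the analysis scaffold (the tree the pipeline assumes).

    The reference pair ("RB" by default) is drawn as sister; under a
    blind-tree-true simulation the data conflict with this scaffold, which is
    exactly the situation the tests probe.
    """
    ref = "(R1,R2)" if config.split_reference else "R"
    return f"((({ref},B),C),O);"


def scaffold_taxa(config: SimulationConfig) -> list:
    base = ["R1", "R2"] if config.split_reference else ["R"]
    return base + ["B", "C", "O"]


def _rng(config, seed=None):
    s = seed if seed is not None else config.seed
    if s is None:
        raise SpecError("a seed is required for reproducible simulation")
    return np.random.default_rng(s)


def _count(rng, mean, fixed):
    if mean <= 0:
        return 0
    return int(round(mean)) if fixed else int(rng.poisson(mean))


def simulate_patterns(config: SimulationConfig, rng=None) -> list:
    """Draw marker origin/pattern pairs before matrix assembly.

    Returns a list of (pattern_name, origin) with origin in
    {"species", "ILS", "introgression"}; patterns not containing the
    reference are already dropped (ascertainment).
    """
    rng = rng if rng is not None else _rng(config)
    T = config.internal_branch_length
    p_discord = np.exp(-T) / 3.0
    mult = config.rate_multipliers
    out = []

    # internal branch of the true species tree
    n_int = _count(
        rng,
        config.intensity.get("internal", 0.0) * mult.get("internal", 1.0),
        config.fixed_counts,
    )
    pair = config.species_pair
    others = [p for p in PAIRS if p != pair]
    if n_int:
        u = rng.random(n_int)
        for x in u:
            if x < p_discord:
                out.append((others[0], "ILS"))
            elif x < 2 * p_discord:
                out.append((others[1], "ILS"))
            else:
                out.append((pair, "species"))

    # terminal branches and the deep stem
    for branch, pattern in (("R", "R"), ("B", "B"), ("C", "C"), ("stem", "RBC")):
        n = _count(
            rng,
            config.intensity.get(branch, 0.0) * mult.get(branch, 1.0),
            config.fixed_counts,
        )
        out.extend([(pattern, "species")] * n)

    # introgression: beta donor-stem insertions predate the event, each
    # shared with the recipient w.p. gamma; alpha postdate it
    intro = config.introgression
    if intro is not None:
        donor, recipient = intro.direction
        n_beta = _count(
            rng, intro.beta * mult.get(f"{donor}_pre", 1.0), config.fixed_counts
        )
        n_alpha = _count(
            rng, intro.alpha * mult.get(f"{donor}_post", 1.0), config.fixed_counts
        )
        shared = rng.random(n_beta) < intro.gamma if n_beta else np.empty(0, bool)
        for s in shared:
            if s:
                key = "".join(sorted(donor + recipient))
                key = {"BR": "RB", "CR": "RC", "BC": "BC"}.get(key, key)
                out.append((key, "introgression"))
            else:
                out.append((donor, "species"))
        out.extend([(donor, "species")] * n_alpha)

    # single-reference ascertainment: only patterns containing R survive
    return [(p, o) for (p, o) in out if "R" in p]


def simulate_matrix(config: SimulationConfig, rng=None):
    """Observable marker matrix plus ground truth.

    Returns (MarkerMatrix, truth) where truth is a list of
    (locus, pattern_name, origin).
    """
    patterns = simulate_patterns(config, rng)
    sets = _leaf_sets(config)
    taxa = scaffold_taxa(config)
    calls = {}
    truth = []
    for i, (pattern, origin) in enumerate(patterns):
        locus = f"L{i + 1:05d}"
        present = sets[pattern]
        calls[locus] = {t: (PRESENT if t in present else ABSENT) for t in taxa}
        truth.append((locus, pattern, origin))
    matrix = MarkerMatrix.from_dict(calls, taxa=taxa, loci=[t[0] for t in truth])
    return matrix, truth


def write_truth(truth, path) -> None:
    """Sidecar TSV: locus, pattern, origin."""
    with open(path, "w") as fh:
        fh.write("locus\tpattern\torigin\n")
        for locus, pattern, origin in truth:
            fh.write(f"{locus}\t{pattern}\t{origin}\n")


# ---------------------------------------------------------------------------
# Pipeline application and calibration
# ---------------------------------------------------------------------------

def _ils_pipeline_count(matrix, tree) -> InsertionCount:
    """polarize -> trichotomy count for the scaffold (R vs B vs C)."""
    polarized = polarize_all(matrix, tree)
    spec = TrifurcationSpec(
        clade_a=frozenset({"R"}),
        clade_b=frozenset({"B"}),
        clade_c=frozenset({"C"}),
        reference_taxon="R",
        tested="ab",
        label="scaffold",
    )
    tally = count_trifurcation(polarized, NodeSpec(label="scaffold", trifurcation=spec), tree)
    return tally.count


def _ratio_pipeline_count(matrix, tree) -> RatioCount:
    polarized = polarize_all(matrix, tree)
    return ratio_count_for_clade(
        polarized, frozenset({"R1", "R2", "B"}), tree, reference_taxon="R1"
    )


@dataclass(frozen=True)
class CalibrationResult:
    test_id: str
    alpha: float
    replicates: int
    rejections: int
    skipped: int  # replicates with no testable markers (counted as non-rejections)

    @property
    def rate(self) -> float:
        return self.rejections / self.replicates

    def confidence_interval(self, level: float = 0.95):
        """Exact (Clopper-Pearson) binomial CI on the rejection rate."""
        k, n = self.rejections, self.replicates
        lo = 0.0 if k == 0 else float(stats.beta.ppf((1 - level) / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1 - (1 - level) / 2, k + 1, n - k))
        return lo, hi


def test_calibration(
    config: SimulationConfig,
    test_id: str,
    alpha: float = 0.05,
    replicates: int = 1000,
    gamma=None,
) -> CalibrationResult:
    """Empirical rejection rate of a test under a simulated scenario.

    Each replicate simulates a matrix, runs the polarize -> count -> test
    pipeline, and records whether the test rejects at ``alpha``.  Replicates
    whose matrix yields no testable markers score as non-rejections (the test
    cannot reject on no data).
    """
    if replicates < 100:
        raise SpecError("use at least 100 replicates for a meaningful rate")
    if test_id not in (bt.ILS_SYMMETRY, bt.INSERTION_RATIO, bt.KKSC_ONEDIR):
        raise SpecError(f"unknown or uncalibratable test {test_id!r}")
    if test_id == bt.INSERTION_RATIO:
        if gamma is None:
            raise SpecError("insertion-ratio calibration needs the test gamma")
        config = replace(config, split_reference=True)
    tree = SpeciesTree.read_newick(scaffold_newick(config))
    seeds = np.random.SeedSequence(config.seed).spawn(replicates)
    alpha_f = bt.as_fraction(alpha)
    rejections = skipped = 0
    for ss in seeds:
        rng = np.random.default_rng(ss)
        matrix, _ = simulate_matrix(config, rng=rng)
        if test_id in (bt.ILS_SYMMETRY, bt.KKSC_ONEDIR):
            count = _ils_pipeline_count(matrix, tree)
            a, b = count.support_t1, count.support_t2
            if a + b < 1:
                skipped += 1
                continue
            if test_id == bt.ILS_SYMMETRY:
                result = bt.ils_symmetry(a, b)
            else:
                result = bt.kksc_onedir(InsertionCount(a, b))
        else:
            ratio = _ratio_pipeline_count(matrix, tree)
            if ratio.total < 1:
                skipped += 1
                continue
            result = bt.insertion_ratio_test(ratio, gamma)
        if result.p_value <= alpha_f:
            rejections += 1
    out = CalibrationResult(test_id, float(alpha), replicates, rejections, skipped)
    log.info(
        "calibration %s: rate=%.4f (%d/%d, %d skipped)",
        test_id, out.rate, rejections, replicates, skipped,
    )
    return out


test_calibration.__test__ = False  # a library entry point, not a pytest case


def blind_ils_null(seed, intensity: float = 10.0, T: float = 1.0) -> SimulationConfig:
    """Blind tree true, all discordance from ILS on the internal branch."""
    return SimulationConfig(
        species_pair="BC",
        internal_branch_length=T,
        intensity={"internal": intensity},
        seed=seed,
    )


def blind_introgression_null(
    seed, beta: float = 8.0, alpha: float = 0.0, gamma: float = 0.5,
    donor_rate: float = 1.0, to_reference: bool = False,
) -> SimulationConfig:
    """Blind tree true, observable sharing donated by introgression.

    By default gene flow runs from the reference lineage's stem to B; the
    bound N = gamma * (d + e) then covers the expectation regardless of
    per-branch insertion rates.  With ``to_reference`` the flow runs B -> R:
    B's pre-event stem donates the shared markers while the reference stem
    accumulates its own (``beta`` expected under equal rates), the one
    configuration whose calibration depends on rate equality.
    ``donor_rate`` scales the donor's pre-event insertion rate (the
    overconfidence scenario is ``to_reference`` with donor_rate > 2).
    """
    if to_reference:
        scenario = IntrogressionScenario(
            alpha=alpha, beta=beta, gamma=gamma, direction=("B", "R")
        )
        return SimulationConfig(
            species_pair="BC",
            internal_branch_length=50.0,  # no ILS: isolate the introgression null
            intensity={"R": beta},  # reference-stem insertions over the same period
            introgression=scenario,
            rate_multipliers={"B_pre": donor_rate} if donor_rate != 1.0 else {},
            seed=seed,
        )
    return SimulationConfig(
        species_pair="BC",
        internal_branch_length=50.0,
        intensity={},
        introgression=IntrogressionScenario(alpha=alpha, beta=beta, gamma=gamma),
        rate_multipliers={"R_pre": donor_rate} if donor_rate != 1.0 else {},
        seed=seed,
    )
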