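"""The three-argument workflow for rejecting the "blind" tree at a node.

A significant one-directional KKSC test only says the two *observable*
resolutions differ in support; the resolution excluding the reference genome
remains untested.  The blind tree is rejected only when both hemiplasy
hypotheses fall:

* H_ILS — blind tree true, observable markers are ILS hemiplasy — rejected by
  the two-tailed ILS symmetry test;
* H_Introgression — blind tree true, observable markers donated by
  introgression — rejected by the insertion ratio test at the decisive genome
  fraction gamma.

A-priori evidence (previous phylogenies, morphology) is carried as free text
into the report and never machine-scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction

from . import bias_tests as bt
from .counts import InsertionCount, RatioCount
from .errors import SpecError

YES = "yes"
NO = "no"
UNTESTED = "untested"


@dataclass(frozen=True)
class DecisionConfig:
    """Thresholds for the node workflow.

    ``trigger``: the ILS and ratio tests are run when P_B <= trigger (the
    follow-up tests are pointless when even the binary preference is weak);
    ``force`` computes them regardless.  ``decisive_gamma`` is the genome
    fraction whose ratio test must reject for the blind tree to fall; gammas
    beyond it are reported but only annotate the verdict.  ``bonferroni``
    optionally divides alpha by the number of nodes scanned (no cross-node
    correction by default).
    """

    alpha: float = 0.05
    trigger: float = 0.1
    gammas: tuple = (Fraction(1, 2), Fraction(1, 5))
    decisive_gamma: Fraction = Fraction(1, 2)
    force: bool = False
    bonferroni: bool = False

    def __post_init__(self):
        gammas = tuple(bt.as_fraction(g) for g in self.gammas)
        object.__setattr__(self, "gammas", gammas)
        object.__setattr__(self, "decisive_gamma", bt.as_fraction(self.decisive_gamma))
        if self.decisive_gamma not in gammas:
            raise SpecError("decisive_gamma must be one of the configured gammas")


DEFAULT_CONFIG = DecisionConfig()


@dataclass
class NodeVerdict:
    """Structured outcome of the blind-tree workflow at one node."""

    node_label: str
    count: InsertionCount
    ratio: RatioCount | None
    results: list  # of bias_tests.TestResult
    blind_rejected: str
    rationale: list
    apriori_note: str | None = None
    topology_t1: str = ""
    topology_t2: str = ""
    topology_blind: str = ""
    ambiguous_added: InsertionCount | None = None

    def result(self, test_id, gamma=None):
        for r in self.results:
            if r.test_id == test_id and (gamma is None or r.gamma == bt.as_fraction(gamma)):
                return r
        return None


def evaluate_node(
    count: InsertionCount,
    ratio: RatioCount | None = None,
    config: DecisionConfig = DEFAULT_CONFIG,
    node_label: str = "",
    apriori: str | None = None,
    n_nodes: int = 1,
) -> NodeVerdict:
    """Run the blind-tree workflow on one trichotomy count.

    Fully observed counts get the multi-directional test only (no blind
    regime).  Blind counts always get the one-directional KKSC test; the ILS
    symmetry and insertion ratio tests run when P_B <= trigger (or forced)
    and a ratio pattern is available.  The blind tree is rejected only when
    both H_ILS and H_Introgression are rejected at level alpha, the latter at
    the decisive gamma.
    """
    alpha = bt.as_fraction(config.alpha)
    if config.bonferroni and n_nodes > 1:
        alpha = alpha / n_nodes
    rationale: list[str] = []
    results = []

    if not count.blind:
        r = bt.kksc_multi(count)
        rationale.append(
            "fully observed count: multi-directional test only, no blind-tree regime"
        )
        return NodeVerdict(node_label, count, ratio, [r], UNTESTED, rationale, apriori)

    r_kksc = bt.kksc_onedir(count)
    results.append(r_kksc)
    triggered = r_kksc.p_value <= bt.as_fraction(config.trigger)
    if not triggered and not config.force:
        rationale.append(
            f"P_B = {bt.format_p(r_kksc.p_value)} > trigger {float(config.trigger):g}: "
            "hemiplasy tests not run"
        )
        return NodeVerdict(node_label, count, ratio, results, UNTESTED, rationale, apriori)
    if not triggered:
        rationale.append("trigger not met; hemiplasy tests forced")

    r_ils = bt.ils_symmetry(count.support_t1, count.support_t2)
    results.append(r_ils)
    ils_rejected = r_ils.p_value <= alpha
    rationale.append(
        f"H_ILS {'rejected' if ils_rejected else 'not rejected'} "
        f"(P_ILS = {bt.format_p(r_ils.p_value)}, alpha = {float(alpha):g})"
    )

    if ratio is None or ratio.total < 1:
        rationale.append("ratio pattern unavailable: H_Introgression untested")
        return NodeVerdict(node_label, count, ratio, results, UNTESTED, rationale, apriori)

    decisive_rejected = False
    moderate_rejected = False
    for gamma in config.gammas:
        r_ratio = bt.insertion_ratio_test(ratio, gamma)
        results.append(r_ratio)
        rejected = r_ratio.p_value <= alpha
        if gamma == config.decisive_gamma:
            decisive_rejected = rejected
            rationale.append(
                f"H_Introgression at decisive gamma={float(gamma):g} "
                f"{'rejected' if rejected else 'not rejected'} "
                f"(P_R = {bt.format_p(r_ratio.p_value)}, N = {float(r_ratio.n_bound):g})"
            )
        else:
            moderate_rejected = moderate_rejected or rejected
            rationale.append(
                f"H_Introgression at gamma={float(gamma):g} "
                f"{'rejected' if rejected else 'not rejected'} "
                f"(P_R = {bt.format_p(r_ratio.p_value)}, N = {float(r_ratio.n_bound):g})"
            )

    if ils_rejected and decisive_rejected:
        verdict = YES
        rationale.append("both H_ILS and H_Introgression rejected: blind tree rejected")
    else:
        verdict = NO
        if ils_rejected and moderate_rejected and not decisive_rejected:
            rationale.append(
                "rejected only under the moderate-introgression assumption; "
                "blind tree retained at the decisive gamma"
            )
        else:
            rationale.append("blind tree not rejected")
    return NodeVerdict(node_label, count, ratio, results, verdict, rationale, apriori)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_DASH = "—"


def _cell(verdict, test_id, gamma=None, decimals=4):
    r = verdict.result(test_id, gamma)
    return bt.format_p(r.p_value, decimals) if r is not None else _DASH


def _report_rows(verdicts, config: DecisionConfig):
    gammas = list(config.gammas)
    header = (
        ["trifurcation", "insertion_pattern", "topology", "P_B", "P_ILS", "ratio_pattern"]
        + [f"P_R{int(round(float(g) * 100))}" for g in gammas]
        + ["blind_rejected"]
    )
    rows = [header]
    for v in verdicts:
        if not v.count.blind:
            p_main = _cell(v, bt.KKSC_MULTI)
        else:
            p_main = _cell(v, bt.KKSC_ONEDIR)
        ratio_txt = str(v.ratio) if (v.ratio and v.result(bt.INSERTION_RATIO)) else _DASH
        topo = v.topology_t1 or _DASH
        row = [
            v.node_label,
            str(v.count),
            topo,
            p_main,
            _cell(v, bt.ILS_SYMMETRY),
            ratio_txt,
        ]
        for g in gammas:
            row.append(_cell(v, bt.INSERTION_RATIO, g))
        row.append(v.blind_rejected)
        rows.append(row)
    return rows


def node_report(verdicts, config: DecisionConfig = DEFAULT_CONFIG, fmt: str = "tsv") -> str:
    """Render verdicts as a table (one row per trichotomy, dashes = not run)."""
    if not verdicts:
        raise SpecError("no verdicts to report")
    rows = _report_rows(verdicts, config)
    if fmt == "tsv":
        return "\n".join("\t".join(r) for r in rows) + "\n"
    if fmt == "markdown":
        out = ["| " + " | ".join(rows[0]) + " |",
               "|" + "|".join(["---"] * len(rows[0])) + "|"]
        out += ["| " + " | ".join(r) + " |" for r in rows[1:]]
        return "\n".join(out) + "\n"
    raise SpecError(f"unknown report format {fmt!r}")


def verdicts_json(verdicts) -> str:
    """JSON dump with exact (unrounded) p-values for auditability."""
    payload = []
    for v in verdicts:
        entry = {
            "node": v.node_label,
            "insertion_pattern": str(v.count),
            "ratio_pattern": str(v.ratio) if v.ratio else None,
            "blind_rejected": v.blind_rejected,
            "rationale": v.rationale,
            "apriori": v.apriori_note,
            "tests": [
                {
                    "test": r.test_id,
                    "gamma": str(r.gamma) if r.gamma is not None else None,
                    "p_exact": str(r.p_value),
                    "p": float(r.p_value),
                    "tail": r.tail,
                    "n_bound": float(r.n_bound) if r.n_bound is not None else None,
                }
                for r in v.results
            ],
        }
        if v.ambiguous_added is not None:
            entry["with_ambiguous"] = str(v.ambiguous_added)
        payload.append(entry)
    return json.dumps(payload, indent=2)
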