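"""One-command reproduction of the full lineup analysis from the packaged
outcome tables: identification rates, chi-square condition contrasts,
pAUC bootstrap Z-tests, confidence-accuracy curves and signal-detection
model fits for every (age group x description condition) cell.

Response-time analyses are omitted here because the packaged frequency
tables carry no trial-level response times; use
:func:`lineup_sdt.reliability.rac` on trial-level data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any

import numpy as np

from .data import BinningScheme, Condition, Group, table2_fixture
from .rates import Outcome, compare_conditions, correct_id_rate, estimated_false_id_rate
from .reliability import bootstrap_accuracy_ci
from .roc import pauc_z_test
from .sdt import dprime, fit

__all__ = ["AnalysisReport", "reproduce_paper_analysis"]

CELLS = [
    (Group.YOUNG, Condition.CONTROL),
    (Group.YOUNG, Condition.EXPERIMENTAL),
    (Group.OLDER, Condition.CONTROL),
    (Group.OLDER, Condition.EXPERIMENTAL),
]

COMPARISONS = [
    ("young_control_vs_older_control", (Group.YOUNG, Condition.CONTROL), (Group.OLDER, Condition.CONTROL)),
    ("young_control_vs_experimental", (Group.YOUNG, Condition.CONTROL), (Group.YOUNG, Condition.EXPERIMENTAL)),
    ("older_control_vs_experimental", (Group.OLDER, Condition.CONTROL), (Group.OLDER, Condition.EXPERIMENTAL)),
]


@dataclass(frozen=True)
class AnalysisReport:
    """Structured results; ``to_json`` is byte-stable for a given seed."""

    payload: dict[str, Any]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.payload, indent=indent, sort_keys=True)

    def __getitem__(self, key: str) -> Any:
        return self.payload[key]

    def human_summary(self) -> str:
        p = self.payload
        lines = ["Lineup identification analysis", "=" * 32, ""]
        lines.append("Identification rates (correct / estimated false):")
        for cell, r in p["rates"].items():
            lines.append(
                f"  {cell:22s} {r['correct_id_rate']:.3f} / "
                f"{r['estimated_false_id_rate']:.4f}"
            )
        lines.append("")
        lines.append("Chi-square condition contrasts (df=1):")
        for name, c in p["chisq"].items():
            lines.append(f"  {name:32s} chi2={c['statistic']:.4f}  p={c['p']:.6f}")
        lines.append("")
        lines.append("pAUC bootstrap Z-tests:")
        for name, c in p["pauc_tests"].items():
            sig = "significant" if c["p"] < p["provenance"]["alpha"] else "n.s."
            lines.append(
                f"  {name:32s} pAUC {c['pauc_1']:.4f} vs {c['pauc_2']:.4f}  "
                f"Z={c['z']:.4f}  p={c['p']:.4f}  [{sig}]"
            )
        lines.append("")
        lines.append("Equal-variance model fits (d'):")
        for cell, f in p["sdt_fits"].items():
            lines.append(f"  {cell:22s} d'={f['dprime']:.3f}  mu_t={f['mu_t']:.3f}")
        return "\n".join(lines)


def _float_list(x) -> list:
    return [None if (isinstance(v, float) and np.isnan(v)) else float(v) for v in x]


def reproduce_paper_analysis(
    seed: int = 1,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    scheme: BinningScheme | None = None,
) -> AnalysisReport:
    """Run the complete analysis pipeline on the packaged outcome tables."""
    scheme = scheme or BinningScheme()
    tables = {f"{g.value}_{c.value}": table2_fixture(g, c) for g, c in CELLS}
    root = np.random.SeedSequence(seed)
    seeds = iter(root.spawn(len(COMPARISONS) + len(CELLS)))

    rates = {
        name: {
            "correct_id_rate": correct_id_rate(t).rate,
            "estimated_false_id_rate": estimated_false_id_rate(t).rate,
            "n_tp": t.n_tp,
            "n_ta": t.n_ta,
        }
        for name, t in tables.items()
    }

    chisq = {}
    for group in (Group.YOUNG, Group.OLDER):
        ctrl = tables[f"{group.value}_control"]
        expt = tables[f"{group.value}_experimental"]
        for outcome in (Outcome.CORRECT_IDS, Outcome.TA_FALSE_ALARMS):
            res = compare_conditions(ctrl, expt, outcome)
            chisq[f"{group.value}_{outcome.value}"] = {
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p,
                "table": [list(r) for r in res.table],
            }

    pauc_tests = {}
    for name, a, b in COMPARISONS:
        s = int(next(seeds).generate_state(1)[0] % 2**31)
        cmp = pauc_z_test(
            tables[f"{a[0].value}_{a[1].value}"],
            tables[f"{b[0].value}_{b[1].value}"],
            scheme,
            n_boot=n_boot,
            seed=s,
        )
        pauc_tests[name] = {
            "pauc_1": cmp.pauc_1,
            "pauc_2": cmp.pauc_2,
            "cutoff": cmp.cutoff,
            "se_diff": cmp.se_diff,
            "z": cmp.z,
            "p": cmp.p,
            "n_boot": cmp.n_boot,
            "seed": s,
        }

    cac_curves = {}
    sdt_fits = {}
    for name, t in tables.items():
        s = int(next(seeds).generate_state(1)[0] % 2**31)
        curve = bootstrap_accuracy_ci(t, scheme, n_boot=n_boot, seed=s)
        cac_curves[name] = {
            "bins": list(curve.bin_labels),
            "accuracy": _float_list(curve.accuracy),
            "ci_low": _float_list(curve.ci_low),
            "ci_high": _float_list(curve.ci_high),
            "n_cid": [int(x) for x in curve.n_cid],
            "n_fid": [int(x) for x in curve.n_fid],
            "seed": s,
        }
        f = fit(t, scheme, equal_variance=True)
        sdt_fits[name] = {
            "mu_t": f.params.mu_t,
            "criteria": list(f.params.criteria),
            "dprime": dprime(f.params),
            "loglik": f.loglik,
            "converged": f.converged,
            "chisq_gof": f.chisq_gof,
            "df_gof": f.df_gof,
        }

    payload = {
        "rates": rates,
        "chisq": chisq,
        "pauc_tests": pauc_tests,
        "cac": cac_curves,
        "sdt_fits": sdt_fits,
        "provenance": {
            "seed": seed,
            "n_boot": n_boot,
            "alpha": alpha,
            "confidence_bins": [list(b) for b in scheme.confidence_bins],
            "rt_bin_edges": list(scheme.rt_bin_edges),
        },
    }
    return AnalysisReport(payload=payload)
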