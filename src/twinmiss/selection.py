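"""Nested-model selection and variance-component reporting.

Workflow: fit the full ACE model and its nested AE/CE/E sub-models, test
each sub-model against ACE by likelihood-ratio test, and select the
best-fitting model as the *non-significant* sub-model (LRT p at or above
``alpha_model``) with the lowest AIC — ACE itself is always a candidate.
The significance of a retained A or C component is then tested by LRT of
the selected model against the E-only model, at a Bonferroni-corrected
threshold ``0.05 / n_tests``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ace import ACEModel, ACEResults
from .data import TwinDataset
from .inference import LRTResult, lrt

__all__ = [
    "ComparisonRow",
    "ComparisonTable",
    "compare_nested",
    "select_best",
    "fit_all_models",
    "component_significance",
    "render_table",
]

_MODEL_ORDER = ("ACE", "AE", "CE", "E")


@dataclass
class ComparisonRow:
    trait: str
    model: str
    aic: float
    lrt: LRTResult | None  # None for the ACE reference row
    a2: float | None
    c2: float | None
    e2: float | None
    ci_a2: tuple | None = None
    ci_c2: tuple | None = None
    ci_e2: tuple | None = None
    selected: bool = False


@dataclass
class ComparisonTable:
    """Nested-model comparison rows for one trait; exactly one selected."""

    rows: list[ComparisonRow] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if sum(r.selected for r in self.rows) != 1:
            raise ValueError("a comparison table must select exactly one row")

    @property
    def selected_row(self) -> ComparisonRow:
        return next(r for r in self.rows if r.selected)


def compare_nested(full: ACEResults, nested: ACEResults) -> LRTResult:
    """LRT of a nested ACE-family fit against the fuller one.

    The statistic ``2 * (LL_full - LL_nested)`` is clipped at zero (the
    unclipped value is kept in ``raw_statistic``); df is the parameter
    difference; p from the chi-square distribution.
    """
    if nested.n_params >= full.n_params:
        raise ValueError(
            f"{nested.model} (k={nested.n_params}) is not nested in "
            f"{full.model} (k={full.n_params})"
        )
    if nested.model_obj.trait != full.model_obj.trait:
        raise ValueError("fits are for different traits")
    return lrt(full.llf, nested.llf, df=full.n_params - nested.n_params)


def fit_all_models(data: TwinDataset, trait: str, want_ci: bool = False):
    """Fit ACE, AE, CE and E on one trait; returns {name: ACEResults}."""
    return {m: ACEModel(data, trait, model=m).fit(want_ci=want_ci) for m in _MODEL_ORDER}


def select_best(fits: dict, alpha_model: float = 0.05):
    """Select the best-fitting model from {model_name: ACEResults}.

    Candidates are ACE plus every nested model whose LRT-vs-ACE p-value is
    at least ``alpha_model`` (i.e. not significantly worse than ACE); the
    candidate with the lowest AIC wins.  AIC ties (within 1e-8) go to the
    model with fewer parameters, then alphabetically.  Returns
    ``(selected_results, ComparisonTable)``.
    """
    missing = [m for m in _MODEL_ORDER if m not in fits]
    if missing:
        raise ValueError(f"missing fits for {missing}")
    full = fits["ACE"]
    trait = full.model_obj.trait

    rows, candidates = [], [("ACE", full)]
    for name in _MODEL_ORDER:
        res = fits[name]
        test = None if name == "ACE" else compare_nested(full, res)
        if test is not None and test.p >= alpha_model:
            candidates.append((name, res))
        comp = res.components
        rows.append(
            ComparisonRow(
                trait=trait,
                model=name,
                aic=res.aic,
                lrt=test,
                a2=comp.a2 if "a2" in res.model_obj.components else None,
                c2=comp.c2 if "c2" in res.model_obj.components else None,
                e2=comp.e2,
                ci_a2=comp.ci_a2,
                ci_c2=comp.ci_c2,
                ci_e2=comp.ci_e2,
            )
        )

    def sort_key(item):
        name, res = item
        return (round(res.aic / 1e-8) * 1e-8, res.n_params, name)

    selected_name = min(candidates, key=sort_key)[0]
    for r in rows:
        r.selected = r.model == selected_name
    return fits[selected_name], ComparisonTable(rows)


def component_significance(
    data: TwinDataset, trait: str, selected_model: str, n_tests: int = 8
):
    """Test the familial component of the selected model against E-only.

    For an AE or CE selection, compares the selected fit with the E model
    (df = 1: the A or C term forced to zero) and applies a Bonferroni
    threshold of ``0.05 / n_tests``.  Returns ``(p, significant, threshold)``.
    """
    if selected_model not in ("AE", "CE"):
        raise ValueError(
            "component significance is defined for AE or CE selections "
            f"(got {selected_model!r})"
        )
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    sel = ACEModel(data, trait, model=selected_model).fit()
    e_only = ACEModel(data, trait, model="E").fit()
    test = compare_nested(sel, e_only)
    threshold = 0.05 / n_tests
    return test.p, bool(test.p < threshold), threshold


# -- rendering ---------------------------------------------------------


def _fmt_component(value, ci):
    if value is None:
        return "—"
    cell = f"{value:.2f}"
    if ci is not None:
        cell += f" [{ci[0]:.2f}; {ci[1]:.2f}]"
    return cell


def _fmt_p(p):
    return "—" if p is None else f"{p:.2g}"


def render_table(table: ComparisonTable, style: str = "text") -> str:
    """Deterministic text or TSV rendering of a comparison table.

    Components and CIs at 2 decimals (``0.53 [0.41; 0.63]``), AIC rounded
    to integer, p at 2 significant figures, dropped components as a dash.
    """
    header = ["trait", "model", "AIC", "LRT", "ddf", "p", "A", "C", "E", "selected"]
    body = []
    for r in table.rows:
        body.append(
            [
                r.trait,
                r.model,
                f"{r.aic:.0f}",
                "—" if r.lrt is None else f"{r.lrt.statistic:.2g}",
                "—" if r.lrt is None else str(r.lrt.df),
                _fmt_p(None if r.lrt is None else r.lrt.p),
                _fmt_component(r.a2, r.ci_a2),
                _fmt_component(r.c2, r.ci_c2),
                _fmt_component(r.e2, r.ci_e2),
                "*" if r.selected else "",
            ]
        )
    if style == "tsv":
        return "\n".join("\t".join(row) for row in [header] + body) + "\n"
    if style != "text":
        raise ValueError(f"unknown style {style!r}")
    widths = [max(len(row[i]) for row in [header] + body) for i in range(len(header))]
    lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in [header] + body
    ]
    lines.insert(1, "-" * max(len(line) for line in lines))
    return "\n".join(lines) + "\n"
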