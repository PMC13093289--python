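"""User-facing model/results interface for the demographic ABC pipeline.

:class:`DemographicInference` is built from an observed alignment and a
model set (a list of candidate demographic scenarios sharing the same
population groups).  ``fit()`` simulates the reference table, runs the
prior-predictive check, performs random-forest scenario choice, and
estimates the event-time parameters of the selected scenario with quantile
regression forests.  The returned :class:`InferenceResults` carries the
vote fractions, posterior probability, error rates, per-parameter medians
and 95% credible intervals (in generations and calendar years), and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abcrf, coalsim
from .scenarios import DemographicScenario, check_valid
from .seqdata import Alignment, load_alignment


class DemographicInference:
    """Coalescent ABC-RF inference of a demographic model set.

    Parameters
    ----------
    alignment : Alignment
        Trimmed observed alignment with population labels and sample ages.
    model_set : list of DemographicScenario
        Candidate scenarios; all must share the same population groups.
    L : int, optional
        Sequence length to simulate; defaults to the alignment length.
    """

    def __init__(self, alignment: Alignment, model_set: list[DemographicScenario],
                 L: int | None = None):
        if not alignment.is_clean:
            raise ValueError("alignment must be trimmed (no gaps/ambiguity) before inference")
        for sc in model_set:
            check_valid(sc)
        self.alignment = alignment
        self.model_set = list(model_set)
        self.L = int(L or alignment.L)
        self.pop_order = model_set[0].pop_labels
        missing = set(self.pop_order) - set(alignment.populations)
        if missing:
            raise ValueError(f"alignment lacks populations used by scenarios: {sorted(missing)}")

    @classmethod
    def from_files(cls, fasta_path, metadata_path, scenario_paths,
                   L: int | None = None) -> "DemographicInference":
        aln = load_alignment(fasta_path, metadata_path)
        scenarios = [DemographicScenario.from_json(p) for p in scenario_paths]
        return cls(aln, scenarios, L=L)

    def observed_summary(self) -> coalsim.SummaryVector:
        return coalsim.summarize(self.alignment, self.pop_order)

    def build_reference_table(self, n_per_scenario: int, seed: int = 0,
                              workers: int = 1) -> abcrf.ReferenceTable:
        return abcrf.build_reference_table(
            self.model_set, n_per_scenario, self.L, seed=seed, workers=workers
        )

    def fit(
        self,
        n_per_scenario: int = 1000,
        n_trees: int = abcrf.DEFAULT_N_TREES,
        seed: int = 0,
        workers: int = 1,
        reference_table: abcrf.ReferenceTable | None = None,
        estimate_parameters: list[str] | str = "times",
        generation_time: float = 7.0,
        check_prior: bool = True,
    ) -> "InferenceResults":
        """Run the full pipeline and return results.

        ``estimate_parameters`` may be an explicit list of parameter names,
        "times" (all event-time parameters of the selected scenario), or
        "none".
        """
        observed = self.observed_summary()
        table = reference_table or self.build_reference_table(
            n_per_scenario, seed=seed, workers=workers
        )
        predictive = (
            abcrf.prior_predictive_pca(table, observed, seed=seed) if check_prior else None
        )
        choice = abcrf.rf_model_choice(table, observed, n_trees=n_trees, seed=seed)
        selected = next(sc for sc in self.model_set if sc.id == choice.selected)

        if estimate_parameters == "times":
            params = [f"t_{ev.name}" for ev in selected.events if ev.time is not None]
        elif estimate_parameters == "none":
            params = []
        else:
            params = list(estimate_parameters)

        sub = table.restrict(selected.id)
        posteriors: dict[str, abcrf.ParameterPosterior] = {}
        times: dict[str, abcrf.TimeEstimate] = {}
        for p in params:
            post = abcrf.rf_estimate_parameter(sub, observed, p, n_trees=n_trees, seed=seed)
            posteriors[p] = post
            if p.startswith("t_"):
                times[p] = abcrf.generations_to_years(post, generation_time)
        return InferenceResults(
            model=self,
            reference_table=table,
            observed=observed,
            predictive_check=predictive,
            model_choice=choice,
            parameter_posteriors=posteriors,
            time_estimates=times,
            generation_time=generation_time,
            seed=seed,
        )


@dataclass
class InferenceResults:
    """Fitted ABC-RF results: scenario choice, posteriors, diagnostics."""

    model: DemographicInference
    reference_table: abcrf.ReferenceTable
    observed: coalsim.SummaryVector
    predictive_check: dict | None
    model_choice: abcrf.ModelChoiceResult
    parameter_posteriors: dict[str, abcrf.ParameterPosterior]
    time_estimates: dict[str, abcrf.TimeEstimate]
    generation_time: float
    seed: int | None = None

    @property
    def selected_scenario(self) -> str:
        return self.model_choice.selected

    @property
    def posterior_probability(self) -> float:
        return self.model_choice.posterior_probability

    def votes_frame(self) -> pd.DataFrame:
        return self.model_choice.votes.rename("vote_fraction").to_frame()

    def parameters_frame(self) -> pd.DataFrame:
        rows = []
        for name, post in self.parameter_posteriors.items():
            row = {
                "parameter": name,
                "median": post.median,
                "ci_2.5%": post.ci_low,
                "ci_97.5%": post.ci_high,
                "global_nmae": post.global_nmae,
                "local_error": post.local_error,
            }
            if name in self.time_estimates:
                te = self.time_estimates[name]
                ka, lo, hi = te.rounded_ka()
                row.update({"median_ka": ka, "ci_low_ka": lo, "ci_high_ka": hi})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        mc = self.model_choice
        lines = [
            "Demographic ABC-RF inference results",
            "=" * 52,
            f"Scenarios compared:       {len(self.model.model_set)}",
            f"Reference table rows:     {self.reference_table.n_rows}",
            f"Trees per forest:         {mc.n_trees}",
            f"Selected scenario:        {mc.selected}",
            f"Posterior probability:    {mc.posterior_probability:.3f}",
            f"Global (prior) error:     {mc.global_error:.3f}",
            f"Local error:              {mc.local_error:.3f}",
            "",
            "Vote fractions:",
        ]
        for sid, v in mc.votes.items():
            lines.append(f"  {sid:<28s} {v:.3f}")
        if self.predictive_check is not None:
            lines.append("")
            lines.append("Prior-predictive check (observed inside scenario cloud):")
            for sid, rep in self.predictive_check["scenarios"].items():
                lines.append(
                    f"  {sid:<28s} hull={rep['inside_hull']} "
                    f"box={rep['inside_percentile_box']}"
                )
        if self.parameter_posteriors:
            lines.append("")
            lines.append(
                f"Parameter posteriors (generation time {self.generation_time:g} y):"
            )
            df = self.parameters_frame()
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
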