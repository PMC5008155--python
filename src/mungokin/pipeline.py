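"""Config-driven end-to-end runs with logging and a consolidated report.

A :class:`PipelineConfig` names the inputs (a directory of canonical CSVs,
or generator parameters for a synthetic run), toggles the four analyses —
inbreeding depression, breeding-pair avoidance, guard-choice avoidance,
and female paternity control (guard success + paired EPP comparison) —
and fixes the permutation count and master seed. ``run_all`` executes the
stages in dependency order (pedigree -> filters -> tests/models), writes
JSON results and CSV intermediates to the output directory, and renders a
Markdown report. A failed stage is recorded and its dependents skipped;
the run is bit-identical under an identical config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import filters, models, paired, permutation
from ._rng import substream
from .pedigree import write_inbreeding_table, write_relatedness_long
from .records import StudyDataset, read_dataset_dir
from .synth import SimulationParams, simulate

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str | None = None         # canonical CSV directory
    simulate: bool = False               # generate inputs instead of reading
    simulation_params: dict = field(default_factory=dict)
    column_map: dict = field(default_factory=dict)
    run_avoidance: bool = True
    run_guarding: bool = True
    run_guard_success: bool = True
    run_epp: bool = True
    run_depression_mass: bool = True
    run_depression_survival: bool = True
    include_natal_variants: bool = False
    n_perms: int = 10_000
    seed: int = 0
    out_dir: str = "mungokin_out"

    def validate(self) -> None:
        if not self.simulate and self.input_dir is None:
            raise ValueError("config needs input_dir or simulate: true")
        if self.simulate and self.input_dir is not None:
            raise ValueError("config cannot set both input_dir and simulate")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input_dir {self.input_dir!r} does not exist")
        if self.n_perms < 1:
            raise ValueError("n_perms must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _load(config: PipelineConfig) -> StudyDataset:
    if config.simulate:
        params = SimulationParams(**config.simulation_params)
        ds, truth = simulate(params, seed=config.seed)
        out = Path(config.out_dir) / "simulated_input"
        ds.write(out)
        with open(Path(config.out_dir) / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, default=str)
        return ds
    return read_dataset_dir(config.input_dir, column_map=config.column_map or None)


def run_all(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns (and writes) the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2)

    report: dict = {"stages": {}, "seed": config.seed}

    def record(stage: str, status: str, payload=None):
        report["stages"][stage] = {"status": status}
        if payload is not None:
            report["stages"][stage]["result"] = payload
        logger.info("stage %-28s %s", stage, status)

    try:
        ds = _load(config)
        record("load", "ok", {"warnings": ds.validation_warnings})
    except Exception as exc:  # hard error before any stage
        record("load", f"failed: {exc}")
        _write_report(report, out)
        raise

    if ds.pedigree is None:
        record("pedigree", "failed: no pedigree provided")
        _write_report(report, out)
        raise ValueError("dataset has no pedigree; downstream stages need one")
    relmat = ds.pedigree.relatedness_matrix()
    inbreeding = ds.pedigree.inbreeding_table()
    write_relatedness_long(relmat, out / "relatedness.csv")
    write_inbreeding_table(inbreeding, out / "inbreeding.csv")
    record("pedigree", "ok", {"n_individuals": len(ds.pedigree)})

    variants = [False, True] if config.include_natal_variants else [False]

    if config.run_avoidance:
        for natal in variants:
            tag = "avoidance_natal" if natal else "avoidance"
            try:
                dyads, rep = filters.breeding_pair_filter(ds, natal_only=natal)
                rand = permutation.BreedingRandomization(dyads, ds, relmat)
                res = permutation.permutation_test(
                    rand,
                    n_perms=config.n_perms,
                    rng=substream(config.seed, tag),
                    analysis_name=tag,
                )
                res.to_json(out / f"{tag}.json")
                rep.to_json(out / f"{tag}_filter.json")
                record(
                    tag,
                    "ok",
                    {
                        "observed_mean": res.observed_mean,
                        "p_one_tailed": res.p_one_tailed,
                        "n_dyads": res.n_dyads,
                    },
                )
            except Exception as exc:
                record(tag, f"failed: {exc}")

    if config.run_guarding:
        for natal in variants:
            tag = "guarding_natal" if natal else "guarding"
            try:
                dyads, rep = filters.guard_pair_filter(ds, natal_only=natal)
                rand = permutation.GuardRandomization(dyads, relmat)
                res = permutation.permutation_test(
                    rand,
                    n_perms=config.n_perms,
                    rng=substream(config.seed, tag),
                    analysis_name=tag,
                )
                res.to_json(out / f"{tag}.json")
                rep.to_json(out / f"{tag}_filter.json")
                record(
                    tag,
                    "ok",
                    {
                        "observed_mean": res.observed_mean,
                        "p_one_tailed": res.p_one_tailed,
                        "n_dyads": res.n_dyads,
                    },
                )
            except Exception as exc:
                record(tag, f"failed: {exc}")

    if config.run_guard_success:
        for natal in variants:
            tag = "guard_success_natal" if natal else "guard_success"
            try:
                frame = models.build_guard_success_frame(
                    ds, relmat, natal_only=natal
                )
                frame.to_csv(out / f"{tag}_frame.csv", index=False)
                fit = models.fit_and_simplify(
                    frame,
                    response="success",
                    fixed=models.GUARD_SUCCESS_FIXED_TERMS,
                    random=models.GUARD_SUCCESS_RANDOM,
                    family="binomial",
                )
                fit.to_json(out / f"{tag}.json")
                record(
                    tag,
                    "ok",
                    {"n_observations": fit.n_observations,
                     "minimal_terms": fit.minimal_terms},
                )
            except Exception as exc:
                record(tag, f"failed: {exc}")

    if config.run_epp:
        for natal in variants:
            tag = "epp_paired_natal" if natal else "epp_paired"
            try:
                epp_rows, rep = filters.identify_epp(
                    ds, relmat, natal_only=natal
                )
                epp_rows.to_csv(out / f"{tag}_pairs.csv", index=False)
                rep.to_json(out / f"{tag}_filter.json")
                payload = {}
                for scope in ("all", "within_group", "extra_group"):
                    try:
                        res = paired.epp_comparison(epp_rows, scope=scope)
                        res.to_json(out / f"{tag}_{scope}.json")
                        payload[scope] = {
                            "t": res.t_statistic,
                            "df": res.degrees_of_freedom,
                            "p": res.p_two_tailed,
                            "mean_difference": res.mean_difference,
                        }
                    except ValueError as exc:
                        payload[scope] = f"not testable: {exc}"
                record(tag, "ok", payload)
            except Exception as exc:
                record(tag, f"failed: {exc}")

    for tag, flag, builder, response, fixed, random, family in (
        (
            "depression_mass",
            config.run_depression_mass,
            models.build_mass_frame,
            "body_mass",
            models.MASS_FIXED_TERMS,
            models.MASS_RANDOM,
            "gaussian",
        ),
        (
            "depression_survival",
            config.run_depression_survival,
            models.build_survival_frame,
            "survived",
            models.SURVIVAL_FIXED_TERMS,
            models.SURVIVAL_RANDOM,
            "binomial",
        ),
    ):
        if not flag:
            continue
        try:
            frame = builder(ds, inbreeding)
            frame.to_csv(out / f"{tag}_frame.csv", index=False)
            fit = models.fit_and_simplify(
                frame,
                response=response,
                fixed=fixed,
                random=random,
                family=family,
            )
            fit.to_json(out / f"{tag}.json")
            record(
                tag,
                "ok",
                {
                    "n_observations": fit.n_observations,
                    "inbreeding_estimate": fit.terms["inbreeding_f"].estimate,
                    "inbreeding_p": fit.terms["inbreeding_f"].p,
                },
            )
        except Exception as exc:
            record(tag, f"failed: {exc}")

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    lines = ["# mungokin pipeline report", ""]
    for stage, info in report["stages"].items():
        mark = "OK " if info["status"] == "ok" else "FAIL"
        lines.append(f"- **{stage}** [{mark}] {info['status']}")
        if isinstance(info.get("result"), dict):
            for k, v in info["result"].items():
                lines.append(f"    - {k}: {v}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
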