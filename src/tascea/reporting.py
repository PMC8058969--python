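"""Scenario file loading/validation, result export and run manifests.

The scenario file is YAML with three top-level sections: ``model`` (horizon,
cycle length, discounting, threshold, conventions, arm roles), ``arms`` (two
arms, each with ``transitions``, ``utilities`` and ``costs``) and an optional
free-form ``metadata`` block.  Every parameter is a ``{base, min, max, dist}``
mapping.  Validation returns the complete list of violations rather than
stopping at the first.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .engine import run_arm
from .errors import ScenarioValidationError
from .outcomes import base_case_report
from .params import (
    Arm,
    ArmTransitionParams,
    CostInputs,
    CostItem,
    COUNTING_CONVENTIONS,
    DISCOUNT_CONVENTIONS,
    ProbParam,
    Scenario,
    UtilitySet,
)
from .sensitivity import DEFAULT_WTP_GRID, ceac, dsa_tornado, psa_run, tornado_frame

__all__ = [
    "load_scenario",
    "validate_scenario",
    "scenario_to_dict",
    "save_scenario",
    "RunManifest",
    "run_all",
]

_MODEL_KEYS = {
    "cycle_length_weeks",
    "n_cycles",
    "annual_discount",
    "wtp_threshold",
    "counting_convention",
    "discount_convention",
    "reference_arm",
    "comparator_arm",
    "psa_seed",
}
_TRANSITION_KEYS = ("progression", "death", "complication")
_UTILITY_KEYS = ("stable", "complication", "progression", "progression_complication", "death")
_PARAM_KEYS = {"base", "min", "max", "dist"}


def _check_param(raw, where, errors, *, bounded=True, kind="probability"):
    if not isinstance(raw, dict):
        errors.append(f"{where}: expected a {{base, min, max, dist}} mapping")
        return None
    unknown = set(raw) - _PARAM_KEYS
    if unknown:
        errors.append(f"{where}: unknown key(s) {sorted(unknown)}")
    if "base" not in raw:
        errors.append(f"{where}: missing 'base'")
        return None
    base = raw["base"]
    lo = raw.get("min", 0.75 * base)
    hi = raw.get("max", min(1.25 * base, 1.0) if bounded else 1.25 * base)
    if not (0 <= lo <= base <= hi):
        errors.append(f"{where}: requires 0 <= min <= base <= max, got "
                      f"min={lo}, base={base}, max={hi}")
        return None
    if bounded and hi > 1:
        errors.append(f"{where}: {kind} max must be <= 1, got {hi}")
        return None
    dist = raw.get("dist", "beta_like" if bounded else "gamma_like")
    if dist not in ("beta_like", "gamma_like"):
        errors.append(f"{where}: unknown distribution {dist!r}")
        return None
    return {"base": float(base), "min": float(lo), "max": float(hi), "dist": dist}


def validate_scenario(source) -> Scenario:
    """Load and validate a scenario from a path, YAML text, or a dict.

    Raises :class:`ScenarioValidationError` carrying *all* violations; never
    returns a partially constructed model.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        raw = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = source
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ScenarioValidationError(["scenario file must contain a mapping"])

    unknown = set(raw) - {"model", "arms", "metadata", "name", "description"}
    if unknown:
        errors.append(f"unknown top-level key(s) {sorted(unknown)}")
    for section in ("model", "arms"):
        if section not in raw:
            errors.append(f"missing section '{section}'")
    if errors:
        raise ScenarioValidationError(errors)

    model = raw["model"]
    unknown = set(model) - _MODEL_KEYS
    if unknown:
        errors.append(f"model: unknown key(s) {sorted(unknown)}")
    counting = model.get("counting_convention", "cycle_start")
    if counting not in COUNTING_CONVENTIONS:
        errors.append(f"model.counting_convention: unknown value {counting!r}")
    discounting = model.get("discount_convention", "annualized")
    if discounting not in DISCOUNT_CONVENTIONS:
        errors.append(f"model.discount_convention: unknown value {discounting!r}")
    n_cycles = model.get("n_cycles", 30)
    if not isinstance(n_cycles, int) or n_cycles < 1:
        errors.append(f"model.n_cycles: must be a positive integer, got {n_cycles}")
    rate = model.get("annual_discount", 0.035)
    if not (0 <= rate < 1):
        errors.append(f"model.annual_discount: must be in [0, 1), got {rate}")
    cyclen = model.get("cycle_length_weeks", 8)
    if cyclen <= 0:
        errors.append(f"model.cycle_length_weeks: must be positive, got {cyclen}")

    arms_raw = raw["arms"]
    if not isinstance(arms_raw, dict) or len(arms_raw) != 2:
        errors.append("arms: exactly two named arms are required")
        raise ScenarioValidationError(errors)
    ref_name = model.get("reference_arm", list(arms_raw)[0])
    cmp_name = model.get("comparator_arm", list(arms_raw)[1])
    for name in (ref_name, cmp_name):
        if name not in arms_raw:
            errors.append(f"model: arm role {name!r} not present in arms section")
    if ref_name == cmp_name:
        errors.append("model: reference and comparator arms must differ")

    arms: dict[str, Arm] = {}
    for arm_name, arm_raw in arms_raw.items():
        unknown = set(arm_raw) - {"transitions", "utilities", "costs"}
        if unknown:
            errors.append(f"arms.{arm_name}: unknown key(s) {sorted(unknown)}")
        for section in ("transitions", "utilities", "costs"):
            if section not in arm_raw:
                errors.append(f"arms.{arm_name}: missing section '{section}'")
        if any(e.startswith(f"arms.{arm_name}") for e in errors):
            continue

        trans = {}
        for key in _TRANSITION_KEYS:
            if key not in arm_raw["transitions"]:
                errors.append(f"arms.{arm_name}.transitions: missing '{key}'")
                continue
            trans[key] = _check_param(
                arm_raw["transitions"][key], f"arms.{arm_name}.transitions.{key}", errors)
        unknown = set(arm_raw["transitions"]) - set(_TRANSITION_KEYS)
        if unknown:
            errors.append(f"arms.{arm_name}.transitions: unknown key(s) {sorted(unknown)}")
        if all(trans.get(k) for k in _TRANSITION_KEYS):
            total = trans["progression"]["base"] + trans["complication"]["base"]
            if total > 1 + 1e-12:
                errors.append(
                    f"arms.{arm_name}.transitions: row infeasible, progression + "
                    f"complication = {total:.6g} > 1")

        utils = {}
        for key in _UTILITY_KEYS:
            if key not in arm_raw["utilities"]:
                errors.append(f"arms.{arm_name}.utilities: missing '{key}'")
                continue
            utils[key] = _check_param(
                arm_raw["utilities"][key], f"arms.{arm_name}.utilities.{key}",
                errors, kind="utility")
        unknown = set(arm_raw["utilities"]) - set(_UTILITY_KEYS)
        if unknown:
            errors.append(f"arms.{arm_name}.utilities: unknown key(s) {sorted(unknown)}")

        costs_raw = arm_raw["costs"]
        known_cost_keys = {
            "items", "multiplicities", "complication_item",
            "exchange_rate_jpy_per_usd", "body_weight_kg", "body_surface_area_m2",
        }
        unknown = set(costs_raw) - known_cost_keys
        if unknown:
            errors.append(f"arms.{arm_name}.costs: unknown key(s) {sorted(unknown)}")
        items = []
        labels = []
        for i, item_raw in enumerate(costs_raw.get("items", [])):
            label = item_raw.get("label")
            if not label:
                errors.append(f"arms.{arm_name}.costs.items[{i}]: missing 'label'")
                continue
            labels.append(label)
            checked = _check_param(
                {k: v for k, v in item_raw.items() if k != "label"},
                f"arms.{arm_name}.costs.items[{label}]", errors, bounded=False)
            if checked:
                items.append((label, checked))
        comp_label = costs_raw.get("complication_item")
        if comp_label and comp_label not in labels:
            errors.append(
                f"arms.{arm_name}.costs: complication_item {comp_label!r} not among items")
        mults = costs_raw.get("multiplicities", {})
        for label, count in mults.items():
            if label not in labels:
                errors.append(
                    f"arms.{arm_name}.costs.multiplicities: unknown item {label!r}")
            elif not isinstance(count, int) or count < 0:
                errors.append(
                    f"arms.{arm_name}.costs.multiplicities[{label}]: must be a "
                    f"non-negative integer, got {count}")

        if not any(e.startswith(f"arms.{arm_name}") for e in errors):
            arms[arm_name] = Arm(
                name=arm_name,
                transitions=ArmTransitionParams(
                    p_progression=_to_prob(trans["progression"]),
                    p_death=_to_prob(trans["death"]),
                    p_complication=_to_prob(trans["complication"]),
                ),
                utilities=UtilitySet(**{k: _to_prob(v) for k, v in utils.items()}),
                costs=CostInputs(
                    items=tuple(
                        CostItem(lb, c["base"], c["min"], c["max"], c["dist"])
                        for lb, c in items
                    ),
                    multiplicities=dict(mults),
                    complication_label=comp_label or "complication management",
                    exchange_rate=costs_raw.get("exchange_rate_jpy_per_usd", 110.05),
                    body_weight_kg=costs_raw.get("body_weight_kg", 65.0),
                    body_surface_area_m2=costs_raw.get("body_surface_area_m2", 1.72),
                ),
            )

    if errors:
        raise ScenarioValidationError(errors)

    return Scenario(
        reference=arms[ref_name],
        comparator=arms[cmp_name],
        cycle_length_weeks=float(cyclen),
        n_cycles=n_cycles,
        annual_discount=float(rate),
        wtp_threshold=float(model.get("wtp_threshold", 117746.0)),
        counting_convention=counting,
        discount_convention=discounting,
        psa_seed=int(model.get("psa_seed", 20210420)),
        metadata=dict(raw.get("metadata", {})),
    )


def _to_prob(checked: dict) -> ProbParam:
    return ProbParam(checked["base"], checked["min"], checked["max"], checked["dist"])


def load_scenario(path) -> Scenario:
    """Alias of :func:`validate_scenario` for file paths."""
    return validate_scenario(Path(path))


def _param_dict(p) -> dict:
    return {"base": p.base, "min": p.min, "max": p.max, "dist": p.dist_label}


def scenario_to_dict(scenario: Scenario) -> dict:
    arms = {}
    for name, arm in scenario.arms.items():
        arms[name] = {
            "transitions": {
                "progression": _param_dict(arm.transitions.p_progression),
                "death": _param_dict(arm.transitions.p_death),
                "complication": _param_dict(arm.transitions.p_complication),
            },
            "utilities": {k: _param_dict(getattr(arm.utilities, k)) for k in _UTILITY_KEYS},
            "costs": {
                "exchange_rate_jpy_per_usd": arm.costs.exchange_rate,
                "body_weight_kg": arm.costs.body_weight_kg,
                "body_surface_area_m2": arm.costs.body_surface_area_m2,
                "complication_item": arm.costs.complication_label,
                "items": [
                    {"label": it.label, "base": it.base, "min": it.min,
                     "max": it.max, "dist": it.dist_label}
                    for it in arm.costs.items
                ],
                "multiplicities": dict(arm.costs.multiplicities),
            },
        }
    return {
        "model": {
            "cycle_length_weeks": scenario.cycle_length_weeks,
            "n_cycles": scenario.n_cycles,
            "annual_discount": scenario.annual_discount,
            "wtp_threshold": scenario.wtp_threshold,
            "counting_convention": scenario.counting_convention,
            "discount_convention": scenario.discount_convention,
            "reference_arm": scenario.reference.name,
            "comparator_arm": scenario.comparator.name,
            "psa_seed": scenario.psa_seed,
        },
        "arms": arms,
        "metadata": dict(scenario.metadata),
    }


def save_scenario(scenario: Scenario, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False, width=100)
    )


class RunManifest:
    """Provenance record written alongside every output directory."""

    def __init__(self, scenario: Scenario, *, scenario_path=None, seeds=None, warnings=None):
        payload = yaml.safe_dump(scenario_to_dict(scenario), sort_keys=True)
        self.data = {
            "package": "tascea",
            "version": __version__,
            "scenario_digest": hashlib.sha256(payload.encode()).hexdigest(),
            "scenario_path": str(scenario_path) if scenario_path else None,
            "seeds": seeds or {},
            "conventions": {
                "counting": scenario.counting_convention,
                "discounting": scenario.discount_convention,
            },
            "wtp_threshold": scenario.wtp_threshold,
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
            "warnings": list(warnings or []),
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2) + "\n")


def run_all(
    scenario: Scenario,
    out_dir,
    *,
    n_draws: int = 1000,
    seed: int | None = None,
    scenario_path=None,
    wtp_grid=DEFAULT_WTP_GRID,
) -> Path:
    """Run the full pipeline and write every artifact as CSV plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    probe.write_text("")
    probe.unlink()

    warnings_list = []
    for arm_name in scenario.arms:
        trace, totals = run_arm(scenario, arm_name)
        df = trace.to_frame()
        df["discount_weight"] = [
            _df_weight(scenario, t) for t in range(scenario.n_cycles + 1)
        ]
        df.to_csv(out / f"trace_{arm_name}.csv")

    result = base_case_report(scenario)
    result.to_frame().to_csv(out / "base_case.csv", index=False)

    entries = dsa_tornado(scenario)
    tornado_frame(entries).to_csv(out / "tornado.csv", index=False)

    psa = psa_run(scenario, n_draws=n_draws, seed=seed)
    psa.draws.to_csv(out / "psa_samples.csv", index=False)
    if psa.n_renormalized:
        warnings_list.append(
            f"{psa.n_renormalized} sampled transition rows renormalized in PSA")

    curve = ceac(psa, wtp_grid)
    curve.to_frame().to_csv(out / "ceac.csv", index=False)

    manifest = RunManifest(
        scenario,
        scenario_path=scenario_path,
        seeds={"psa": psa.seed},
        warnings=warnings_list,
    )
    manifest.write(out / "manifest.json")
    return out


def _df_weight(scenario: Scenario, t: int) -> float:
    from .engine import discount_factor

    return discount_factor(
        t, scenario.annual_discount, scenario.cycle_length_weeks,
        scenario.discount_convention,
    )
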