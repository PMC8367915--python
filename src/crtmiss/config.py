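"""Study configuration: a YAML description of a design comparison run.

Example file::

    m_range: [1, 20]
    rho: 0.05
    r: 0.95
    d: 0.2
    alpha: 0.05
    sided: two
    t_max: 56
    dropout:
      control: {omega: 0.2, gamma: 2.0}
      intervention: {omega: 0.1, gamma: 2.0}
    mode: expected          # or: sampled
    draws: 1000
    seed: 1
    designs:
      - {scheme: "Mo,Tu,We,Th,Fr", weeks: 4, clusters: 10}
      - {scheme: "Mo,Tu,We,Th,Fr", weeks: 4, clusters: 15}

Omitting the ``dropout`` block (or setting both omegas to zero) evaluates
the designs without dropout.  CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .design import DesignError, TestSpec, TrialDesign, make_design
from .dropout import DropoutModel
from .variance import CorrelationStructure

__all__ = ["StudyConfig", "load_config"]


@dataclass
class StudyConfig:
    """Validated inputs for a multi-design comparison."""

    designs: list[TrialDesign]
    m_range: range
    corr: CorrelationStructure
    test: TestSpec
    dropout_by_arm: tuple[DropoutModel, DropoutModel] | None = None
    mode: str = "expected"
    draws: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.designs) <= 5:
            raise DesignError(
                f"designs: between 1 and 5 designs expected, got {len(self.designs)}"
            )
        if self.mode not in ("expected", "sampled"):
            raise DesignError(f"mode: 'expected' or 'sampled', got {self.mode!r}")
        if self.dropout_by_arm is not None:
            t_max = self.dropout_by_arm[0].t_max
            for design in self.designs:
                if design.last_day > t_max:
                    raise DesignError(
                        f"design ending on day {design.last_day} exceeds "
                        f"t_max={t_max}"
                    )

    def manifest(self) -> dict:
        """Machine-readable echo of the configuration for the run manifest."""
        out = {
            "designs": [
                {
                    "scheme": str(d.scheme),
                    "weeks": d.weeks,
                    "clusters": d.clusters,
                }
                for d in self.designs
            ],
            "m_range": [self.m_range.start, self.m_range.stop - 1],
            "rho": self.corr.rho,
            "r": self.corr.r,
            "d": self.test.d,
            "alpha": self.test.alpha,
            "sided": self.test.sided,
            "mode": self.mode,
            "draws": self.draws,
            "seed": self.seed,
        }
        if self.dropout_by_arm is not None:
            out["dropout"] = {
                arm_name: {"omega": m.omega, "gamma": m.gamma, "t_max": m.t_max}
                for arm_name, m in zip(
                    ("control", "intervention"), self.dropout_by_arm
                )
            }
        return out


def _collect_errors(fn, errors, label):
    try:
        return fn()
    except DesignError as exc:
        errors.append(f"{label}: {exc}")
        return None


def load_config(path, overrides: dict | None = None) -> StudyConfig:
    """Load and validate a YAML study configuration.

    All field-level validation failures are aggregated into a single error
    message so a bad file is diagnosed in one pass.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    errors: list[str] = []

    m_lo, m_hi = raw.get("m_range", [1, 20])
    m_range = range(int(m_lo), int(m_hi) + 1)
    if len(m_range) < 1:
        errors.append(f"m_range: empty range {raw.get('m_range')!r}")

    corr = _collect_errors(
        lambda: CorrelationStructure(
            float(raw.get("rho", 0.05)), float(raw.get("r", 1.0))
        ),
        errors,
        "correlation",
    )
    test = _collect_errors(
        lambda: TestSpec(
            float(raw.get("d", 0.2)),
            float(raw.get("alpha", 0.05)),
            str(raw.get("sided", "two")),
        ),
        errors,
        "test",
    )

    designs = []
    for i, spec in enumerate(raw.get("designs", []), start=1):
        design = _collect_errors(
            lambda spec=spec: make_design(
                spec["scheme"], int(spec["weeks"]), int(spec["clusters"])
            ),
            errors,
            f"design {i}",
        )
        if design is not None:
            designs.append(design)
    if not designs:
        errors.append("designs: at least one design is required")

    dropout_by_arm = None
    drop = raw.get("dropout")
    if drop:
        t_max = int(raw.get("t_max") or max(7 * d.weeks for d in designs or []))

        def build(arm_name):
            arm = drop.get(arm_name, {})
            return DropoutModel(
                float(arm.get("omega", 0.0)), float(arm.get("gamma", 1.0)), t_max
            )

        control = _collect_errors(lambda: build("control"), errors, "dropout.control")
        interv = _collect_errors(
            lambda: build("intervention"), errors, "dropout.intervention"
        )
        if control is not None and interv is not None:
            if control.omega > 0 or interv.omega > 0:
                dropout_by_arm = (control, interv)

    if errors:
        raise DesignError("invalid configuration:\n  " + "\n  ".join(errors))

    return StudyConfig(
        designs=designs,
        m_range=m_range,
        corr=corr,
        test=test,
        dropout_by_arm=dropout_by_arm,
        mode=str(raw.get("mode", "expected")),
        draws=int(raw.get("draws", 1000)),
        seed=raw.get("seed"),
    )
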