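"""Schema-validated run configuration (pydantic, unknown keys rejected)."""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortConfig(_Strict):
    n_per_group: int = Field(7, ge=2)
    noise_sd: float = Field(0.02, ge=0)
    ami_afferent_mean: float = 10.5
    ami_afferent_sd: float = 2.3
    ctl_afferent_mean: float = 0.09
    ctl_afferent_sd: float = 1.8


class SpindleConfig(_Strict):
    baseline: float = Field(10.0, ge=0)
    k_len: float = Field(333.0, ge=0)
    k_vel: float = Field(13.5, ge=0)
    p: float = Field(0.5, gt=0)
    k_act: float = Field(5.0, ge=0)


class ControllerConfig(_Strict):
    virtual_stiffness: float = Field(0.45, ge=0)   # Nm/deg
    virtual_damping: float = Field(0.02, ge=0)     # Nm s/deg
    tau_max: float = Field(162.0, gt=0)            # Nm
    tau_iso_pf: float = Field(180.0, gt=0)
    tau_iso_df: float = Field(45.0, gt=0)


class RunConfig(_Strict):
    """Top-level configuration for a reproducible pipeline run."""

    seed: int = 0
    out_dir: str = "results"
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    spindle: SpindleConfig = Field(default_factory=SpindleConfig)
    controller: ControllerConfig = Field(default_factory=ControllerConfig)
    comparison_families: dict[str, list[str]] = Field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import json
        from pathlib import Path

        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data)
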