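"""Run configuration: schema-validated YAML with per-stage parameter
blocks. Unknown keys are rejected; flags given on the command line take
precedence over config values, which take precedence over these defaults."""

from __future__ import annotations

import yaml
from pydantic import BaseModel, ConfigDict


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TrimParams(_Block):
    min_q: int = 20
    window: int = 4
    min_len: int = 40


class MergeParams(_Block):
    min_overlap: int = 20
    max_mismatch_frac: float = 0.1


class AlignParams(_Block):
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


class SpectrumParams(_Block):
    max_del: int = 30
    p_geom: float = 0.5
    ins_frac: float = 0.2
    tsv: str | None = None


class FilterParams(_Block):
    k: int = 15
    max_edit: int = 2
    min_support: int = 2
    cluster_window: int = 10
    min_flank: int = 20


class RunConfig(_Block):
    seed: int = 0
    trim: TrimParams = TrimParams()
    merge: MergeParams = MergeParams()
    align: AlignParams = AlignParams()
    spectrum: SpectrumParams = SpectrumParams()
    filter: FilterParams = FilterParams()


def load_config(path: str | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
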