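"""Validated configuration objects for the simulator and CLI.

All stochastic behaviour flows from a single integer ``seed`` stored in
:class:`ReactionConfig`; substreams for strand lengths, rNMP placement,
background lability, binomial labelling and lane noise are spawned
deterministically from it.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator


class ReactionConfig(BaseModel):
    """Parameters of one synthesis + hydrolysis reaction.

    Parameters
    ----------
    template_length
        Length of the single-stranded template in nt. Synthesis products are
        truncated here: a complete pass over a circular template is modelled
        as one full-length linear product.
    n_strands
        Number of product molecules to simulate.
    stop_prob
        Per-nucleotide probability ``q`` that synthesis terminates after the
        current nucleotide. Product lengths are geometric with this hazard,
        truncated at ``template_length``.
    rnmp_prob
        Per-nucleotide probability ``p_r`` of embedding a ribonucleotide.
        This is the quantity the analysis reports as "1 rNMP per N nt".
    background_lability_prob
        Per-nucleotide probability of an alkali-labile site of non-rNMP
        origin (e.g. ATP incorporated by contaminating activities); acts
        independently of ``rnmp_prob``.
    label_density
        Fraction of positions carrying radiolabel; label signal of a
        fragment is proportional to length times this density.
    labeling_mode
        ``deterministic`` sets signal = length * label_density exactly (the
        length correction is then exactly invertible); ``binomial`` draws
        signal ~ Binomial(length, label_density).
    seed
        Master seed for every random draw in the reaction.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    template_length: int = Field(ge=1)
    n_strands: int = Field(ge=1)
    stop_prob: float = Field(default=0.0, ge=0.0, lt=1.0)
    rnmp_prob: float = Field(default=0.0, ge=0.0, lt=1.0)
    background_lability_prob: float = Field(default=0.0, ge=0.0, lt=1.0)
    label_density: float = Field(default=1.0, gt=0.0, le=1.0)
    labeling_mode: Literal["deterministic", "binomial"] = "deterministic"
    seed: int = Field(default=0, ge=0)


class RenderConfig(BaseModel):
    """Gel-lane rendering parameters (migration units are arbitrary, mm-like)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    resolution: float = Field(default=0.02, gt=0.0,
                              description="grid spacing, position units per sample")
    band_sigma: float = Field(default=0.1, gt=0.0,
                              description="Gaussian band width (position units)")
    noise_sd: float = Field(default=0.0, ge=0.0,
                            description="additive intensity noise SD (0 = noiseless)")


class LadderAnchor(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    size_nt: float = Field(gt=0.0)
    position: float


# Default three-anchor ladder spanning 100-10,000 nt, one decade per 10
# position units (larger fragments migrate less).
DEFAULT_LADDER: tuple[tuple[float, float], ...] = (
    (10_000.0, 10.0),
    (1_000.0, 20.0),
    (100.0, 30.0),
)


class SimulationConfig(BaseModel):
    """Top-level JSON config for ``ribogel simulate``. Unknown keys rejected."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    reaction: ReactionConfig
    render: RenderConfig = RenderConfig()
    ladder: tuple[LadderAnchor, ...] = tuple(
        LadderAnchor(size_nt=s, position=p) for s, p in DEFAULT_LADDER
    )

    @model_validator(mode="after")
    def _ladder_ok(self) -> "SimulationConfig":
        if len(self.ladder) < 2:
            raise ValueError("ladder: at least 2 anchors required")
        return self


def config_hash(model: BaseModel) -> str:
    """Stable sha256 over the canonical JSON form of a config."""
    payload = json.dumps(model.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
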