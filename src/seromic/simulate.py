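"""Spot-level measurement simulator.

The generative model per (sample, channel, antigen):

    latent log-signal  t = mu_antigen + channel/specimen offset + planted effect + N(0, s_bio)
    replicate r:       signal_r = exp(t + N(0, s_rep))
                       bg_r ~ N(bg_mean, bg_sd) truncated at 0
                       foreground_median = bg_r + signal_r
                       local_background  = max(0, bg_r + N(0, bg_est_sd))

so the background-subtracted net intensity recovers ``signal_r`` up to the
(small) background-estimation noise.  Planted effects and the broad
polyspecific ("sticky") elevation act multiplicatively, specified as log2
fold-changes.  Every (sample, channel) pair draws from its own substream of
the global seed, so adding samples or channels never perturbs the draws of
existing ones.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import channels_of
from .panel import AntigenPanel

_LN2 = math.log(2.0)

SPOT_TABLE_COLUMNS = [
    "sample_id",
    "channel",
    "antigen_id",
    "replicate_index",
    "block",
    "row",
    "column",
    "foreground_median",
    "local_background",
    "flag",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A group/channel-specific elevation of one antigen.

    ``log2_fc`` is the log2 fold-elevation of the latent signal;
    ``penetrance`` is the probability that an individual affected sample
    actually carries the elevation (1.0 = every sample in the group).
    """

    group: str
    channel: str
    antigen_id: str
    log2_fc: float
    penetrance: float = 1.0


@dataclass
class EffectSpec:
    """Noise levels and planted biology of a simulated study.

    The baseline emulates non-specific background binding of a tight,
    single-batch assay: a log-normal latent signal (between-sample log-sd
    ``baseline_log_sd``) with independent per-replicate log-normal spot
    noise (``replicate_log_sd``).  Per-antigen baseline offsets
    (``antigen_log_sd``) give each feature its own characteristic level
    without affecting per-antigen thresholding.
    """

    planted_effects: list[PlantedEffect] = field(default_factory=list)
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 0.025
    replicate_log_sd: float = 0.03
    antigen_log_sd: float = 0.30
    background_mean: float = 100.0
    background_sd: float = 15.0
    background_estimation_sd: float = 5.0
    psa_elevation: float = 3.0  # log2 fold, applied to 81-150 random antigens
    psa_n_range: tuple[int, int] = (81, 150)
    # specimen/channel multiplicative baseline offsets (natural-log scale):
    # tissue is IgA-dominant (~5x IgA over IgG), serum is IgG-dominant (~5x).
    specimen_channel_log_offset: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "tissue": {"IgA": math.log(5.0), "IgA1": math.log(5.0), "IgA2": math.log(5.0)},
            "serum": {"IgG": math.log(5.0), "IgG1": math.log(5.0), "IgG2": math.log(5.0),
                      "IgG3": math.log(5.0), "IgG4": math.log(5.0)},
        }
    )

    def validate(self, panel: AntigenPanel) -> None:
        if self.baseline_log_sd <= 0:
            raise ValueError("baseline_log_sd must be > 0")
        known = set(panel.antigen_ids)
        bad = sorted({e.antigen_id for e in self.planted_effects} - known)
        if bad:
            raise ValueError(f"planted antigens not in panel: {bad}")
        for e in self.planted_effects:
            if not 0.0 <= e.penetrance <= 1.0:
                raise ValueError("penetrance must lie in [0, 1]")


def simulate_spot_table(
    panel: AntigenPanel,
    cohort: pd.DataFrame,
    effects: EffectSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a long-format spot table for every (sample, channel, spot).

    ``seed`` defaults to the seed the cohort was built with; the result is
    byte-identical for identical inputs.
    """
    effects = effects or EffectSpec()
    effects.validate(panel)
    if seed is None:
        seed = int(cohort.attrs.get("seed", 0))
    channels = channels_of(cohort)
    if not channels:
        raise ValueError("cohort carries no detection channels (psa_* columns)")

    spot_geom = panel.spots.sort_values(["antigen_id", "replicate_index"], kind="stable")
    ids = list(spot_geom["antigen_id"].to_numpy()[:: panel.n_replicates])
    n_ant = len(ids)
    id_index = {a: k for k, a in enumerate(ids)}
    # geometry arrays aligned to (antigen, replicate) raveled order
    geom = spot_geom.set_index(["antigen_id", "replicate_index"])
    n_rep = panel.n_replicates

    # per-antigen baseline offsets: one shared stream so all samples see the
    # same antigen-specific levels
    rng_panel = np.random.default_rng([seed, 0xA17])
    antigen_offset = rng_panel.normal(0.0, effects.antigen_log_sd, size=n_ant)

    # planted effect lookup: (group, channel) -> list of (antigen index, log fc, penetrance)
    planted: dict[tuple[str, str], list[tuple[int, float, float]]] = {}
    for e in effects.planted_effects:
        planted.setdefault((e.group, e.channel), []).append(
            (id_index[e.antigen_id], e.log2_fc * _LN2, e.penetrance)
        )

    blocks = geom["block"].to_numpy()
    rows_g = geom["row"].to_numpy()
    cols_g = geom["column"].to_numpy()
    ordered_ids = np.repeat(
        spot_geom["antigen_id"].to_numpy()[::n_rep], n_rep
    )
    rep_idx = np.tile(np.arange(n_rep), n_ant)

    frames = []
    for s_idx, samp in enumerate(cohort.itertuples(index=False)):
        for c_idx, ch in enumerate(channels):
            rng = np.random.default_rng([seed, 1 + s_idx, c_idx])
            mu = effects.baseline_log_mean + antigen_offset
            off = effects.specimen_channel_log_offset.get(samp.specimen, {})
            mu = mu + off.get(ch, 0.0)
            eff = np.zeros(n_ant)
            for k, logfc, pen in planted.get((samp.group, ch), []):
                if pen >= 1.0 or rng.random() < pen:
                    eff[k] += logfc
            if bool(getattr(samp, f"psa_{ch}", False)):
                lo, hi = effects.psa_n_range
                n_psa = min(int(rng.integers(lo, hi + 1)), n_ant)
                sticky = rng.choice(n_ant, size=n_psa, replace=False)
                eff[sticky] += effects.psa_elevation * _LN2
            latent = rng.normal(mu + eff, effects.baseline_log_sd)
            signal = np.exp(
                latent[:, None] + rng.normal(0.0, effects.replicate_log_sd, size=(n_ant, n_rep))
            )
            bg = np.clip(
                rng.normal(effects.background_mean, effects.background_sd, size=(n_ant, n_rep)),
                0.0,
                None,
            )
            local_bg = np.clip(
                bg + rng.normal(0.0, effects.background_estimation_sd, size=(n_ant, n_rep)),
                0.0,
                None,
            )
            fg = bg + signal
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": samp.sample_id,
                        "channel": ch,
                        "antigen_id": ordered_ids,
                        "replicate_index": rep_idx,
                        "block": blocks,
                        "row": rows_g,
                        "column": cols_g,
                        "foreground_median": fg.ravel(),
                        "local_background": local_bg.ravel(),
                        "flag": 0,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out[SPOT_TABLE_COLUMNS]
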