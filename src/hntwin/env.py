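"""Three-step sequential treatment-decision environment.

Wraps the trained patient generator (VAE) and the predictor chain behind the
standard agent-environment interface: ``reset(seed)`` samples one synthetic
patient's pre-treatment profile; three discrete actions then choose
definitive surgery (binary), induction chemotherapy (binary), and the
radiotherapy class (ternary).  Intermediate steps fill in the predicted
stage outcomes (e.g. surgical pathology after surgery) so later decisions
can be state-dependent; the final step runs the full chain rollout.

The reward is a configurable package construct (no canonical clinical reward
exists): 0 for intermediate steps and, at the end of the episode,
``-relapse_weight * P(relapse_yr3) - symptom_weight * mean(end-of-RT symptom
burden) / 10``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain import TwinChain
from .schema import SYMPTOMS
from .vae import VaeModel, sample_patients

DS_LABELS = ("no", "yes")
IC_LABELS = ("no", "yes")
RC_LABELS = ("no", "yes", "yes-with-concurrent-chemotherapy")


@dataclass
class RewardConfig:
    relapse_weight: float = 1.0
    symptom_weight: float = 1.0
    symptoms: tuple[str, ...] = tuple(f"mdasi_endrt_{s}" for s in SYMPTOMS)


@dataclass
class EpisodeState:
    step_index: int = 0
    record: pd.Series | None = None

    @property
    def done(self) -> bool:
        return self.step_index >= 3


class TreatmentEnv:
    """reset/step environment with discrete action spaces (2, 2, 3)."""

    action_sizes = (2, 2, 3)

    def __init__(self, vae: VaeModel, chain: TwinChain,
                 reward: RewardConfig | None = None, mode: str = "expected"):
        self.vae = vae
        self.chain = chain
        self.reward = reward or RewardConfig()
        self.mode = mode
        self.state: EpisodeState | None = None
        self._episode_seed = 0
        self.ptf_columns = [f.name for f in vae.schema]

    def reset(self, seed: int = 0) -> pd.Series:
        """Sample one synthetic pre-treatment profile; returns the PTF-only
        observation."""
        patient = sample_patients(self.vae, 1, seed=seed)
        record = pd.Series(np.nan, index=self.chain.schema.names, dtype=object)
        row = patient.values.iloc[0]
        record[row.index] = row.values
        self.state = EpisodeState(0, record)
        self._episode_seed = seed
        return self._observation()

    def _observation(self) -> pd.Series:
        rec = self.state.record
        return rec[rec.notna()].copy()

    def _predict_stage(self, targets: list[str]) -> None:
        rec = self.state.record
        rng_seed = self._episode_seed
        for target in targets:
            spec = self.chain.schema[target]
            mp = spec.missing_policy
            if (mp.kind == "structural"
                    and rec[mp.condition_feature] not in mp.condition_values):
                continue
            node = self.chain.nodes[target]
            X = self.chain._matrix(rec.to_frame().T, node.parents)
            if node.task == "regression":
                pred = float(self.chain.encoder.normalizer.invert_series(
                    target, np.asarray(node.model.predict(X), float))[0])
                if self.mode == "sampled":
                    rng = np.random.default_rng(
                        [rng_seed, zlib.crc32(target.encode()) & 0x7FFFFFFF])
                    pred += float(rng.normal(0.0, node.residual_sd))
                if spec.bounds is not None:
                    lo, hi = spec.bounds
                    pred = float(np.clip(pred,
                                         lo if lo is not None else -np.inf,
                                         hi if hi is not None else np.inf))
                rec[target] = pred
            else:
                probs = node.model.predict_proba(X)[0]
                rec[target] = node.classes[int(np.argmax(probs))]

    def step(self, action: int) -> tuple[pd.Series, float, bool, dict]:
        if self.state is None:
            raise RuntimeError("call reset() before step()")
        if self.state.done:
            raise RuntimeError("episode is done; call reset()")
        step = self.state.step_index
        n_actions = self.action_sizes[step]
        if not (isinstance(action, (int, np.integer)) and 0 <= action < n_actions):
            raise ValueError(
                f"action {action!r} out of range for step {step} "
                f"(expected 0..{n_actions - 1})")
        rec = self.state.record
        info: dict = {}
        reward = 0.0
        if step == 0:
            rec["definitive"] = DS_LABELS[action]
            self._predict_stage(["ENE", "Margin"])
        elif step == 1:
            rec["induction"] = IC_LABELS[action]
        else:
            rec["radio/chemo"] = RC_LABELS[action]
            ptf = rec[self.ptf_columns]
            result = self.chain.rollout(
                ptf,
                {"definitive": rec["definitive"],
                 "induction": rec["induction"],
                 "radio_chemo": rec["radio/chemo"]},
                mode=self.mode, seed=self._episode_seed)
            self.state.record = rec = result.record
            burden = float(np.mean([float(rec[s]) for s in self.reward.symptoms]))
            reward = (-self.reward.relapse_weight * result.relapse_prob
                      - self.reward.symptom_weight * burden / 10.0)
            info = {"record": rec.copy(),
                    "relapse_prob": result.relapse_prob,
                    "endrt_burden": burden}
        self.state.step_index += 1
        return self._observation(), reward, self.state.done, info

    # -- plan comparison ----------------------------------------------------
    def run_plan(self, plan: tuple[int, int, int], seed: int) -> dict:
        self.reset(seed=seed)
        for action in plan:
            _, reward, done, info = self.step(action)
        assert done
        return {"reward": reward, **info}


def compare_plans(env: TreatmentEnv, plan_a: tuple[int, int, int],
                  plan_b: tuple[int, int, int], n_episodes: int = 100,
                  seed: int = 0) -> dict:
    """Paired comparison of two treatment plans on shared synthetic patients.

    Both plans are applied to the same generated profiles (identical episode
    seeds), so differences isolate the treatment effect.  Returns per-plan
    mean predicted relapse probability and mean end-of-RT symptom burden,
    plus the paired differences.
    """
    for plan in (plan_a, plan_b):
        for step, action in enumerate(plan):
            if not 0 <= action < env.action_sizes[step]:
                raise ValueError(f"illegal action {action} at step {step}")
    rows = {"a": [], "b": []}
    for i in range(n_episodes):
        ep_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                      % (2 ** 31))
        rows["a"].append(env.run_plan(plan_a, ep_seed))
        rows["b"].append(env.run_plan(plan_b, ep_seed))

    def agg(key):
        return {k: float(np.mean([r[key] for r in v])) for k, v in rows.items()}

    relapse = agg("relapse_prob")
    burden = agg("endrt_burden")
    reward = agg("reward")
    return {
        "plan_a": {"actions": list(plan_a), "relapse_prob": relapse["a"],
                   "endrt_burden": burden["a"], "reward": reward["a"]},
        "plan_b": {"actions": list(plan_b), "relapse_prob": relapse["b"],
                   "endrt_burden": burden["b"], "reward": reward["b"]},
        "paired_diff": {
            "relapse_prob": relapse["b"] - relapse["a"],
            "endrt_burden": burden["b"] - burden["a"],
            "reward": reward["b"] - reward["a"],
        },
        "n_episodes": n_episodes,
    }


#: the two published extreme plans: conservative (radiotherapy alone) and
#: aggressive (surgery + induction + chemoradiation)
PLAN_CONSERVATIVE = (0, 0, 1)
PLAN_AGGRESSIVE = (1, 1, 2)
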