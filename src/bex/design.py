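"""Trial-design generation for the S1-S2 boundary-extension paradigm.

Each participant sees 512 stimulus-test pairs in 8 blocks of 64; every block
holds 16 trials of each pair type (CC, WW, CW, WC), in randomized order.  The
256 scenes are assigned to pair types anew for every participant, and every
scene is used in exactly two trials.  The response hand alternates between
block halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, ...] = ("CC", "WW", "CW", "WC")


@dataclass(frozen=True)
class DesignSpec:
    n_subjects: int = 23
    n_blocks: int = 8
    trials_per_condition_per_block: int = 16
    conditions: tuple[str, ...] = CONDITIONS
    n_scenes: int = 256
    s1_duration_ms: float = 250.0
    mask_duration_ms: float = 500.0  # Methods value; configurable
    fixation_ms: float = 800.0
    seed: int = 0

    @property
    def trials_per_block(self) -> int:
        return len(self.conditions) * self.trials_per_condition_per_block

    @property
    def total_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def trials_per_condition(self) -> int:
        return self.n_blocks * self.trials_per_condition_per_block

    def validate(self) -> None:
        if self.n_scenes * 2 != self.total_trials:
            raise ValueError(
                f"n_scenes * 2 = {self.n_scenes * 2} must equal total trials "
                f"{self.total_trials} (every scene is used in exactly two trials)"
            )
        if self.trials_per_condition % 2:
            raise ValueError(
                "trials per condition must be even: each scene's two trials "
                "belong to one pair type")
        if set(self.conditions) != set(CONDITIONS):
            raise ValueError(f"conditions must be a permutation of {CONDITIONS}")

    def scaled(self, trials_per_condition_per_block: int, **kw) -> "DesignSpec":
        """Same design at a smaller per-block trial count (scenes rescaled)."""
        n_blocks = kw.pop("n_blocks", self.n_blocks)
        total = n_blocks * len(self.conditions) * trials_per_condition_per_block
        from dataclasses import replace
        return replace(self, trials_per_condition_per_block=trials_per_condition_per_block,
                       n_blocks=n_blocks, n_scenes=total // 2, **kw)


def generate_design(spec: DesignSpec = DesignSpec(), rng: np.random.Generator | None = None
                    ) -> pd.DataFrame:
    """Randomized per-subject trial table.

    Returns one row per trial with columns (subject, block, trial, condition,
    scene, hand).  Within each block the condition order is randomized; the
    scene-to-condition assignment is randomized per subject; each scene id
    appears in exactly two trials of the same condition (its S1 and S2
    presentations belong to one pair type, shown in two different blocks).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    k = len(spec.conditions)
    tpc = spec.trials_per_condition  # trials per condition per subject
    rows = []
    for subj in range(1, spec.n_subjects + 1):
        # Assign scenes to conditions: tpc/2 scenes per condition, each seen twice.
        scenes = rng.permutation(spec.n_scenes)
        per_cond = spec.n_scenes // k
        cond_scene: dict[str, np.ndarray] = {}
        for i, cond in enumerate(spec.conditions):
            s = scenes[i * per_cond:(i + 1) * per_cond]
            cond_scene[cond] = rng.permutation(np.repeat(s, 2))
        used = {c: 0 for c in spec.conditions}
        for block in range(1, spec.n_blocks + 1):
            labels = np.repeat(np.arange(k), spec.trials_per_condition_per_block)
            rng.shuffle(labels)
            hand = "left" if ((block - 1) < spec.n_blocks // 2) ^ (subj % 2 == 0) else "right"
            for t, lab in enumerate(labels, start=1):
                cond = spec.conditions[lab]
                scene = cond_scene[cond][used[cond]]
                used[cond] += 1
                rows.append((subj, block, t, cond, int(scene), hand))
    return pd.DataFrame(rows, columns=["subject", "block", "trial", "condition",
                                       "scene", "hand"])
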