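"""Version-controlled experiment recipes.

Each preset bundles a network, a rule, an episode budget and a task-source
recipe into a reproducible experiment.  ``*-bench`` presets mirror the
full-scale benchmark protocol (5-layer 784-170-130-100-70-47 network, 5-way
episodes with K=50 train / Q=10 query per class); ``scaled`` variants shrink
the network and episode budget so the same pipelines run in seconds.

By default presets draw episodes from the synthetic prototype source; pass a
directory of IDX files (``data_dir``) to run on a real dataset such as the
47-class handwritten-character benchmark instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .meta import MetaConfig
from .network import NetworkConfig
from .plasticity import named_rule
from .tasks import (SyntheticTaskSpec, make_synthetic_source, episode_sampler,
                    load_idx_source)

PAPER_LAYERS = (784, 170, 130, 100, 70, 47)
SCALED_LAYERS = (64, 40, 30, 20, 5)


@dataclass
class ExperimentPreset:
    name: str
    rule_name: str
    feedback_mode: str
    layer_sizes: tuple
    episodes: int
    M: int = 5
    K: int = 50
    Q: int = 10
    l1_lambda: float = 0.0
    meta_learning_rate: float = 1e-3
    synthetic_spec: SyntheticTaskSpec = None

    def build(self, data_seed: int = 0, data_dir: str = None,
              episodes: int = None, trial_seed: int = 0):
        """Return ``(MetaConfig, task_sampler)`` ready for meta-training."""
        if data_dir is not None:
            root = Path(data_dir)
            source = load_idx_source(root / "images-idx3-ubyte", root / "labels-idx1-ubyte")
        else:
            spec = self.synthetic_spec or SyntheticTaskSpec(
                input_dim=self.layer_sizes[0],
                class_pool_size=max(20, self.layer_sizes[-1]))
            if spec.input_dim != self.layer_sizes[0]:
                # layer sizes were overridden after the preset was defined
                import dataclasses
                spec = dataclasses.replace(spec, input_dim=self.layer_sizes[0])
            source = make_synthetic_source(spec, seed=data_seed)
        sampler = episode_sampler(source, self.M, self.K, self.Q)
        config = MetaConfig(
            network=NetworkConfig(self.layer_sizes, feedback_mode=self.feedback_mode),
            rule=named_rule(self.rule_name),
            episodes=self.episodes if episodes is None else episodes,
            meta_learning_rate=self.meta_learning_rate,
            l1_lambda=self.l1_lambda,
            trial_seed=trial_seed,
        )
        return config, sampler


_SCALED_SPEC = SyntheticTaskSpec(input_dim=64, class_pool_size=20, n_per_class=60)

PRESETS = {
    # Full-scale benchmark recipes (single-coefficient baselines, composite rules)
    "bp-bench": ExperimentPreset("bp-bench", "fa_baseline", "BP", PAPER_LAYERS, 600),
    "fa-bench": ExperimentPreset("fa-bench", "fa_baseline", "FA", PAPER_LAYERS, 600),
    "pool-bench": ExperimentPreset("pool-bench", "pool", "FA", PAPER_LAYERS, 600,
                                   l1_lambda=1e-3),
    "ehebb-bench": ExperimentPreset("ehebb-bench", "ehebb", "FA", PAPER_LAYERS, 600),
    "oja-bench": ExperimentPreset("oja-bench", "oja", "FA", PAPER_LAYERS, 600),
    "bio-bench": ExperimentPreset("bio-bench", "bio", "FA", PAPER_LAYERS, 600),
    # Scaled-down variants for quick qualitative reproduction
    "bp-scaled": ExperimentPreset("bp-scaled", "fa_baseline", "BP", SCALED_LAYERS, 100,
                                  K=10, synthetic_spec=_SCALED_SPEC),
    "fa-scaled": ExperimentPreset("fa-scaled", "fa_baseline", "FA", SCALED_LAYERS, 100,
                                  K=10, synthetic_spec=_SCALED_SPEC),
    "ehebb-scaled": ExperimentPreset("ehebb-scaled", "ehebb", "FA", SCALED_LAYERS, 100,
                                     K=10, synthetic_spec=_SCALED_SPEC),
    "oja-scaled": ExperimentPreset("oja-scaled", "oja", "FA", SCALED_LAYERS, 100,
                                   K=10, synthetic_spec=_SCALED_SPEC),
    "pool-scaled": ExperimentPreset("pool-scaled", "pool", "FA", SCALED_LAYERS, 100,
                                    K=10, l1_lambda=1e-3, synthetic_spec=_SCALED_SPEC),
}
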