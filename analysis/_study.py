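"""Shared setup for the analysis drivers: the seed-1 reference study."""

from pathlib import Path

import stemcnv.synthetic_data as sd

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def reference_study():
    cfg = sd.SyntheticStudyConfig(seed=SEED)
    gm = sd.generate_gene_model(cfg)
    net = sd.generate_network(cfg, gm)
    truth = sd.make_truth(cfg, gm, net)
    return cfg, gm, net, truth


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
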