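"""Shared settings for the analysis drivers.

Study scale for the drivers: 20 planted SCAs x 5 ZCTAs with 3 hospitals
per SCA (60 hospitals) over 2012-2017, within-SCA discharge rate 20 vs 0.3
across SCAs (realized LI around 0.8, as in real discharge data).  The
larger 300-hospital condition used for coefficient-recovery checks lives
in sharedcare.experiments.recovery_config.
"""

from pathlib import Path

from sharedcare import SyntheticConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"
NETWORKS = RESULTS / "networks"
PARTITIONS = RESULTS / "partitions"

SEED = 20120406
ALGORITHMS = ("louvain", "slpa", "mapeq")

STUDY_CONFIG = SyntheticConfig(
    n_scas=20,
    zctas_per_sca=5,
    hospitals_per_sca=3,
    between_rate=0.3,
    seed=SEED,
)
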