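import numpy as np
import pytest

import switchscope as ss
from switchscope.lineage import CellRecord, build_pedigree


@pytest.fixture(scope="session")
def small_switch_cfg():
    """Reduced trap experiment for fast unit tests."""
    return ss.SwitchModelConfig(n_traps=8, trap_capacity=120)


@pytest.fixture(scope="session")
def small_flow_cfg():
    """Reduced flow plate (fewer events per well) for fast unit tests."""
    return ss.FlowModelConfig(events_per_well=800)


def make_static_pedigree(names, n_frames=2, class_label="white"):
    recs = [CellRecord(cell_id=n, trap_id="t", birth_frame=0,
                       end_frame=n_frames - 1,
                       meta=dict(class_label=class_label, birth_time_min=0.0))
            for n in names]
    return build_pedigree(recs, trap_id="t")


@pytest.fixture(scope="session")
def separated_cells_movie():
    """Five well-separated white cells rendered with mild noise."""
    cfg = ss.SwitchModelConfig(n_frames=2)
    ped = make_static_pedigree(["0", "0.1", "0.2", "0.1.1", "0.2.1"])
    movie, masks, gt = ss.render_movie(
        ped, cfg, canvas_shape=(640, 640), spacing=2.4,
        noise_sd=0.02, dic_noise_sd=1.0, seed=5)
    assert len(gt.label_map) == 5, "fixture must render all five cells"
    return cfg, movie, masks, gt
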