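import numpy as np
import pytest

from noduleco import (ImageRecord, SpecimenRecord, SurveyDataset, qc_filter)
from noduleco.bootstrap import SpecimenIndex
from noduleco.simulate import preset_config, simulate_survey


def make_image(i, cover, transect="flat-t00", landscape="flat", altitude=3.0,
               area=1.71, junction=False, seq=None):
    return ImageRecord(
        image_id=f"img{i:04d}", transect_id=transect, landscape=landscape,
        sequence_index=i if seq is None else seq, altitude=altitude,
        area=area, cover=cover, junction_flag=junction)


def make_specimen(i, image_id, species="actiniaria-msp1", group="metazoan",
                  habit="NA", feeding="suspension", length=2.0, biovol=0.5):
    return SpecimenRecord(
        specimen_id=f"sp{i:05d}", image_id=image_id, morphospecies=species,
        group=group, life_habit=habit, feeding=feeding,
        body_length=length, biovolume=biovol if group == "metazoan" else None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """6 images along a cover gradient with a hand-placed specimen layout."""
    images = [make_image(i, cover) for i, cover in
              enumerate([0.0, 1.0, 2.5, 5.0, 10.0, 20.0])]
    specimens = []
    layout = {  # image index -> (species, count)
        0: [("porifera-msp5", 3)],
        1: [("porifera-msp5", 2), ("actiniaria-msp1", 1)],
        2: [("actiniaria-msp1", 2), ("xeno-msp1", 2)],
        3: [("actiniaria-msp1", 3), ("isidid-msp1", 1)],
        4: [("isidid-msp1", 2), ("xeno-msp1", 3)],
        5: [("isidid-msp1", 3)],
    }
    n = 0
    for i, specs in layout.items():
        for species, count in specs:
            group = "xenophyophore" if species.startswith("xeno") else "metazoan"
            for _ in range(count):
                specimens.append(make_specimen(
                    n, f"img{i:04d}", species=species, group=group))
                n += 1
    return SurveyDataset(images=images, specimens=specimens)


@pytest.fixture
def tiny_index(tiny_dataset):
    return SpecimenIndex.build(tiny_dataset.images, tiny_dataset.specimens,
                               focal_group="metazoan")


@pytest.fixture(scope="session")
def desk_survey():
    """One QC-filtered desk-scale saturating survey, shared across tests."""
    ds = simulate_survey(preset_config("saturating_stock", seed=7))
    return ds.subset_images(qc_filter(ds.images))
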