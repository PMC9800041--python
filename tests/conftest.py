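import imageio.v3 as iio
import numpy as np
import pytest

from annotassist.core import ProjectMeta, TaskKind, create_project


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_png(path, array):
    iio.imwrite(path, np.asarray(array, dtype=np.uint8))


@pytest.fixture
def blob_project(tmp_path):
    """A small on-disk instance-segmentation project with three blob images."""
    from annotassist.synthetic import BlobSpec, make_blobs

    image_dir = tmp_path / "images"
    image_dir.mkdir()
    truth = {}
    for i in range(3):
        img, inst, sem, seeds = make_blobs(BlobSpec(n_blobs=3, seed=100 + i))
        write_png(image_dir / f"blob_{i}.png", img)
        truth[f"blob_{i}"] = (inst, seeds)
    meta = ProjectMeta(
        name="blobs",
        task=TaskKind.instance_segmentation,
        class_names=["cell"],
        image_dir="images",
        annotation_dir="annotations",
    )
    project = create_project(tmp_path, meta)
    return project, truth
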