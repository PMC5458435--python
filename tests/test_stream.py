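import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mammroi import (
    SegParams,
    default_seg_params,
    first_run_bounds,
    generate_phantom,
    kernel_background,
    kernel_pectoral,
    process_batch,
    remove_background_reference,
    remove_pectoral_reference,
    segment_reference,
    segment_stream,
)
from mammroi.phantom import PhantomSpec
from mammroi.stream import _stream_background, _stream_pectoral

from helpers import random_image, random_params

images = hnp.arrays(
    dtype=np.uint32,
    shape=st.tuples(st.integers(1, 12), st.integers(1, 12)),
    elements=st.integers(0, 20),
)


@pytest.mark.parametrize(
    "row, expected",
    [
        ([0, 5, 5, 0, 7], (1, 2)),
        ([0, 0, 0], None),
        ([9, 0, 9], (0, 0)),
        ([3, 3, 3], (0, 2)),
    ],
)
def test_first_run_bounds_examples(row, expected):
    run = first_run_bounds(row, black=1)
    assert (run if run is None else tuple(run)) == expected


@settings(deadline=None, derandomize=True)
@given(hnp.arrays(np.uint32, st.integers(1, 30), elements=st.integers(0, 9)), st.integers(1, 9))
def test_first_run_bounds_matches_naive_scan(row, black):
    naive = None
    for c, v in enumerate(row):
        if v >= black:
            if naive is None:
                naive = [c, c]
            elif naive[1] == c - 1:
                naive[1] = c
    run = first_run_bounds(row, black)
    assert (run if run is None else list(run)) == naive


def test_background_kernel_single_row_keeps_only_first_run():
    out = kernel_background(np.array([[0, 5, 5, 0, 7]]), SegParams(black=1))
    assert np.array_equal(out, [[0, 5, 5, 0, 0]])


def test_background_kernel_two_row_toy_removes_detached_column():
    img = np.array([[0, 9, 9, 0, 4], [0, 9, 9, 0, 4]], dtype=np.uint32)
    params = SegParams(black=1)
    expect = np.array([[0, 9, 9, 0, 0], [0, 9, 9, 0, 0]])
    assert np.array_equal(kernel_background(img, params), expect)
    assert np.array_equal(remove_background_reference(img, params), expect)


def test_background_kernel_matches_reference_on_phantoms():
    for seed in range(20):
        spec = PhantomSpec(rows=40, cols=40, seed=seed, n_artifacts=seed % 4)
        ph = generate_phantom(spec)
        params = default_seg_params(spec)
        assert np.array_equal(
            kernel_background(ph.image, params),
            remove_background_reference(ph.image, params),
        ), f"seed {seed}"


@settings(deadline=None, derandomize=True, max_examples=60)
@given(images, st.integers(1, 8), st.integers(1, 19))
def test_pectoral_kernel_is_the_reference_recurrence_on_any_image(img, black, threshold):
    params = SegParams(black=black, threshold=threshold)
    assert np.array_equal(
        kernel_pectoral(img, params), remove_pectoral_reference(img, params)
    )


def test_pectoral_kernel_identity_and_all_hot_cases(rng):
    cold = rng.integers(0, 50, size=(11, 5)).astype(np.uint32)
    assert np.array_equal(kernel_pectoral(cold, SegParams(threshold=60)), cold)
    hot = rng.integers(60, 90, size=(11, 5)).astype(np.uint32)
    assert not kernel_pectoral(hot, SegParams(threshold=60)).any()


@settings(deadline=None, derandomize=True, max_examples=50)
@given(images, st.integers(1, 8), st.integers(1, 19))
def test_kernels_are_idempotent_and_pass_through_or_black(img, black, threshold):
    params = SegParams(black=black, threshold=threshold)
    for kern in (kernel_background, kernel_pectoral):
        once = kern(img, params)
        assert np.all((once == img) | (once == 0))
        assert np.array_equal(kern(once, params), once)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(images, st.integers(1, 8))
def test_first_run_pixels_are_never_removed_by_background_kernel(img, black):
    out = kernel_background(img, SegParams(black=black))
    for r in range(img.shape[0]):
        run = first_run_bounds(img[r], black)
        if run is not None:
            sl = slice(run.start, run.end + 1)
            assert np.array_equal(out[r, sl], img[r, sl])


def test_segment_stream_equals_reference_on_phantoms_and_is_idempotent():
    for seed in range(10):
        spec = PhantomSpec(rows=48, cols=48, seed=seed)
        ph = generate_phantom(spec)
        params = default_seg_params(spec)
        out = segment_stream(ph.image, params)
        assert np.array_equal(out, segment_reference(ph.image, params))
        assert np.array_equal(segment_stream(out, params), out)


def test_segment_stream_handles_left_view(small_phantom, small_params):
    mirrored = small_phantom.image[:, ::-1]
    left = segment_stream(mirrored, small_params.with_(view="left"))
    right = segment_stream(small_phantom.image, small_params)
    assert np.array_equal(left, right[:, ::-1])


class _OneShotRows:
    """Iterator that refuses to yield any row twice (streaming contract)."""

    def __init__(self, image):
        self._rows = iter(np.asarray(image))
        self.reads = 0

    def __iter__(self):
        return self

    def __next__(self):
        self.reads += 1
        return next(self._rows)


def test_kernels_read_each_row_exactly_once(rng):
    img = rng.integers(0, 99, size=(17, 9)).astype(np.uint32)
    src = _OneShotRows(img)
    out = np.stack(list(_stream_background(src, black=3)))
    assert src.reads == img.shape[0] + 1  # rows + the StopIteration probe
    assert np.array_equal(out, kernel_background(img, SegParams(black=3)))
    src = _OneShotRows(img)
    out = np.stack(list(_stream_pectoral(src, black=3, threshold=50, boundary_row=2)))
    assert src.reads == img.shape[0] + 1
    assert np.array_equal(
        out, kernel_pectoral(img, SegParams(black=3, threshold=50, pectoral_fraction=2 / 17))
    )


def test_batch_rejects_more_than_eight_images(small_phantom):
    with pytest.raises(ValueError, match="eight"):
        process_batch([small_phantom.image] * 9)


def test_batch_is_elementwise_segment_stream(rng):
    assert process_batch([]) == []
    imgs = [random_image(rng, max_side=24, max_value=120) for _ in range(5)]
    params = random_params(rng, max_value=120)
    results = process_batch(imgs, params)
    assert len(results) == 5
    for img, res in zip(imgs, results):
        assert np.array_equal(res, segment_stream(img, params))
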