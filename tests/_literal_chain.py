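"""Independent straight-line re-execution of the published segmentation chain.

This is a deliberate transcript of the documented operation sequence, built
directly from scipy/skimage primitives with no code shared with the
package: 2-D (non-separable) correlation with explicitly constructed
truncated Gaussian windows, the distance-transform watershed split with
h-minima depth 1, the exact-disk dilation for ROIs, and the three-clause
marker masks.  Tests compare the package's outputs bit-for-bit against it.
"""

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.morphology import reconstruction
from skimage.segmentation import watershed


def gauss2d(size, sigma):
    ax = np.arange(size, dtype=float) - (size - 1) / 2.0
    k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def filt(image, size, sigma):
    """Correlation with the full 2-D window, mirror padding, via FFT.

    The anchor sits at index ``size // 2`` of the window, so the image is
    padded by ``c = size // 2`` before and ``size - 1 - c`` after each axis
    and the flipped kernel is applied in 'valid' mode.
    """
    im = np.asarray(image, float)
    k = gauss2d(size, sigma)
    c = size // 2
    padded = np.pad(im, ((c, size - 1 - c), (c, size - 1 - c)), mode="symmetric")
    return fftconvolve(padded, k[::-1, ::-1], mode="valid")


def nuclei_mask(nuc):
    dog = filt(nuc, 10, 2) - filt(nuc, 60, 20)
    return dog > 50


def split_ridges(mask):
    dist = ndimage.distance_transform_edt(mask)
    neg = -dist  # complement of the distance map up to an affine shift
    # suppress minima shallower than 1 via reconstruction by dilation
    hm = -reconstruction(-neg - 1.0, -neg, method="dilation",
                         footprint=np.ones((3, 3), bool))
    ws = watershed(hm, connectivity=2, watershed_line=True)
    return ws == 0


def nuclei_labels(mask):
    ridges = split_ridges(mask)
    labels, n = ndimage.label(mask & ~ridges, structure=np.ones((3, 3), int))
    return labels, n


def roi_regions(mask):
    """Disk-dilated mask cut by the ridges; returns the raw region labels."""
    r = 10
    ax = np.arange(-r, r + 1)
    disk = (ax[:, None] ** 2 + ax[None, :] ** 2) <= r * r
    dilated = ndimage.binary_dilation(mask, structure=disk)
    ridges = split_ridges(mask)
    regions, _ = ndimage.label(dilated & ~ridges, structure=np.ones((3, 3), int))
    return regions


def marker_mask(channel, fine_thr, big_thr, global_thr):
    ch = np.asarray(channel, float)
    dog_fine = filt(ch, 11, 1) - filt(ch, 11, 3)
    dog_big = filt(ch, 99, 3) - filt(ch, 99, 11)
    med = ndimage.median_filter(ch, size=3, mode="constant", cval=0.0)
    return (dog_fine > fine_thr) | (dog_big > big_thr) | (med > global_thr)
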