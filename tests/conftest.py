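import numpy as np
import pytest

from adrenoct import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def iso_ellipsoid():
    """Ellipsoid semi-axes (15, 5, 4) mm digitised at 0.2 mm isotropic."""
    spec = PhantomSpec(shape="ellipsoid", semi_axes_mm=(15.0, 5.0, 4.0),
                       spacing=(0.2, 0.2, 0.2))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def iso_sphere_r5():
    spec = PhantomSpec(shape="ellipsoid", semi_axes_mm=(5.0, 5.0, 5.0),
                       spacing=(0.2, 0.2, 0.2))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def dumbbell():
    """Two lobes (r 6 and 5 mm) joined by a 2.5 mm neck, 0.4 mm isotropic."""
    spec = PhantomSpec(shape="dumbbell", lobe_radii_mm=(6.0, 5.0),
                       neck_radius_mm=2.5, lobe_separation_mm=18.0,
                       spacing=(0.4, 0.4, 0.4))
    return make_phantom(spec)


def make_dicom_series(directory, n_slices=4, stored_value=1104, rows=8,
                      pixel_spacing=(0.5, 0.5), with_pixel_spacing=True):
    """Write a minimal synthetic axial DICOM series for I/O tests."""
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory.mkdir(parents=True, exist_ok=True)
    for i in range(n_slices):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = generate_uid()
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Rows = ds.Columns = rows
        if with_pixel_spacing:
            ds.PixelSpacing = list(pixel_spacing)
        ds.SliceThickness = 2.0
        ds.ImagePositionPatient = [0.0, 0.0, 2.0 * i]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.InstanceNumber = i + 1
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        arr = np.full((rows, rows), stored_value, dtype=np.uint16)
        ds.PixelData = arr.tobytes()
        ds.save_as(str(directory / f"{i:03d}.dcm"), enforce_file_format=True)
    return directory
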