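import base64

import numpy as np
import pytest
from hypothesis import settings

from phenolannot.library import load_library
from phenolannot.rules import default_catalogue
from phenolannot.simulate import fixture_spectra

settings.register_profile("ci", deadline=None, derandomize=True, database=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def fixture_specs(library):
    """The 44 compounds as noiseless spectra at exact theoretical m/z."""
    return fixture_spectra(library)


def _b64(arr) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def _spectrum_xml(idx, mslevel, prec, mzs, ints, rt_min) -> str:
    prec_xml = ""
    if mslevel == 2:
        prec_xml = f"""
        <precursorList count="1"><precursor>
          <selectedIonList count="1"><selectedIon>
            <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{prec}"/>
            <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="1"/>
          </selectedIon></selectedIonList>
        </precursor></precursorList>"""
    return f"""
    <spectrum index="{idx}" id="scan={idx + 1}" defaultArrayLength="{len(mzs)}">
      <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{mslevel}"/>
      <cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>
      <scanList count="1"><scan>
        <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_min}" unitName="minute"/>
      </scan></scanList>{prec_xml}
      <binaryDataArrayList count="2">
        <binaryDataArray>
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
          <binary>{_b64(mzs)}</binary>
        </binaryDataArray>
        <binaryDataArray>
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
          <binary>{_b64(ints)}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>"""


def write_minimal_mzml(path, spectra) -> None:
    """spectra: list of (mslevel, precursor_mz, mzs, ints, rt_minutes)."""
    body = "".join(_spectrum_xml(i, *s) for i, s in enumerate(spectra))
    xml = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="run1">
    <spectrumList count="{len(spectra)}">{body}
    </spectrumList>
  </run>
</mzML>"""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(xml)
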