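"""Verify the indole-isonitrile intermediate by exact mass.

The early intermediate of the hapalindole pathway, 3-(2-isocyanovinyl)-
indole, has the molecular formula C11H8N2.  High-resolution MS verifies
a candidate peak against the neutral monoisotopic mass; low-resolution
negative-mode LC-MS sees the [M-H] ion at the nominal m/z.
"""

from hapalocompare import monoisotopic_mass, nominal_ion_mz, ppm_difference

expected = monoisotopic_mass("C11H8N2")
print(f"monoisotopic mass of C11H8N2: {expected:.4f} Da")
print(f"nominal [M-H] m/z:            {nominal_ion_mz('C11H8N2', 'M-H')}")

# a measured parent-ion peak, compared to the expectation in ppm
observed = 168.0689
print(f"observed {observed:.4f} vs expected {expected:.4f}: "
      f"{ppm_difference(observed, expected):.2f} ppm")
# ~1 ppm agreement is well inside QTOF accuracy: the peak is consistent
# with the indole-isonitrile.
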