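"""Call microsatellite instability for one sample from fragment profiles.

Builds paired tumor/normal allele-length histograms for the 8 STR loci,
forces three markers to show a novel shorter dominant allele (the unstable
pattern), and prints the per-marker calls and the sample-level status.
With 3 of 8 markers unstable the sample crosses the >= 30% threshold and
is called MSI-High.
"""

from ecsubtype.msi import call_sample
from ecsubtype.synthetic import MARKER_LENGTHS

unstable_markers = {"BAT26", "BAT25", "NR21"}
tumor, normal = {}, {}
for marker, length in MARKER_LENGTHS.items():
    normal[marker] = {length: 1000.0, length - 1: 400.0}   # allele + stutter
    if marker in unstable_markers:
        tumor[marker] = {length: 700.0, length - 5: 800.0}  # novel short allele
    else:
        tumor[marker] = dict(normal[marker])

profile = call_sample("EXAMPLE", tumor, normal)
for marker, call in profile.marker_calls.items():
    print(f"{marker:<8} {call}")
print(f"unstable fraction: {profile.unstable_fraction:.3f} "
      f"-> status {profile.msi_status}")
print("A marker is unstable when a dominant tumor allele sits more than "
      "2 bp from every dominant normal allele.")
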