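"""Credential LC-MS features as biological and read off their C/N composition.

A feature is of biological origin when a fully 13C-fed culture shows the
same retention time with an m/z shift of nC carbon-isotope mass differences;
the matching shift in a 15N-fed culture counts the nitrogens.  Here we plant
UDP-xylose (C14H22N2O16P2), glucose (C6H12O6, nitrogen-free), and a solvent
contaminant, then credential them.
"""

from isodiel import Feature, credential_features, labeled_mz, mz_deprotonated


def peak(fid, mz, rt, sample):
    return Feature(feature_id=fid, sample_id=sample, mz=mz, rt_min=rt, area=1e5)


control = [
    peak("udp-xylose", mz_deprotonated("C14H22N2O16P2"), 6.0, "CTRL"),
    peak("glucose", mz_deprotonated("C6H12O6"), 2.0, "CTRL"),
    peak("contaminant", 413.2661, 9.1, "CTRL"),
]
c13 = [
    peak("a", labeled_mz("C14H22N2O16P2", "13C")[0], 6.0, "C13"),
    peak("b", labeled_mz("C6H12O6", "13C")[0], 2.0, "C13"),
    peak("c", 413.2661, 9.1, "C13"),  # unshifted: not biological
]
n15 = [
    peak("d", labeled_mz("C14H22N2O16P2", "15N")[0], 6.0, "N15"),
    peak("e", mz_deprotonated("C6H12O6"), 2.0, "N15"),  # no N, no shift
    peak("f", 413.2661, 9.1, "N15"),
]

for result in credential_features(control, c13, n15):
    print(
        f"{result.feature_id:12s} biological={str(result.biological):5s} "
        f"nC={result.n_carbon} nN={result.n_nitrogen}"
    )
# UDP-xylose credentials with its true composition (nC=14, nN=2), glucose
# with nC=6 and nN=0; the contaminant shows no 13C shift and is rejected.
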