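"""Physical constants and unit conversions.

Internal unit system is atomic units (hartree, bohr, hbar = m_e = 1) on
mass-weighted coordinates, so the nuclear Hamiltonian is H = P^2/2 + V(R)
with no explicit masses.  The user-facing interface accepts eV and fs.
"""

HARTREE_EV = 27.211386  # 1 hartree in eV
AU_TIME_FS = 0.02418884  # 1 a.u. of time in fs
HBAR_EVFS = 0.6582119  # hbar in eV*fs


def ev_to_au(x: float) -> float:
    return x / HARTREE_EV


def au_to_ev(x: float) -> float:
    return x * HARTREE_EV


def fs_to_au(t: float) -> float:
    return t / AU_TIME_FS


def au_to_fs(t: float) -> float:
    return t * AU_TIME_FS
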