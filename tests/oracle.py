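"""Independent, naive transcription of the governing equations.

This module re-derives the 33 state derivatives directly from the published
table of governing equations and rate laws, written as literally as possible
(one line per printed expression, parameters addressed by their printed
symbols) and sharing no code with the package implementation.  It exists only
as a cross-check oracle for the flux-assembly tests.
"""

import numpy as np

SYM = dict(
    Ve=0.2, Vcap=0.0055, Vg=0.25, Vn=0.45, xi=0.07,
    SmVn=2.5e4, SmVg=2.5e4, F=9.64853e4, RTF=26.73, psig=-70.0, Nae=150.0,
    KtGLCen=8.0, KtGLCeg=8.0, KtGLCcg=8.0, KtGLCce=8.0,
    KtLACne=0.74, KtLACge=3.5, KtLACgc=1.0, KtLACec=1.0,
    KIATP=1.0, nH=4.0, Kg=0.05,
    KO2=0.0361, HbOP=8.6, nh=2.73, KO2mito=0.001,
    Cm=1e-3, gL=0.02, gNa=40.0, gK=18.0, gCa=0.02, gmAHP=6.5,
    KD=30e-3, tauCa=150e-3, Ca0=0.5e-4, EK=-80.0, ECa=120.0, phin=4.0, phih=4.0,
    tauv=35.0, alphav=0.5, F0=0.012, Vv0=0.02, O2a=8.35, GLCa=4.75,
    gNan=0.0136, gNag=0.0061, gKpas=0.2035,
    kpumpn=2.2e-6, kpumpg=4.5e-7, Jpump0g=0.0687, Kmpump=0.5, Na0=8.0,
    C=10.0, N=0.212, A=2.212, qAK=0.92, Kmmito=0.04,
    kLDHpn=72.3, kLDHpg=1.59,
    Mcyton=4.9e-8, Mcytog=2.5e-4, Mmiton=3.93e5, Mmitog=1.06e4,
    KmADPn=3.41e-3, KmADPg=0.483e-3, KmNADHn=4.44e-2, KmNADHg=2.69e-2,
    kCKpn=0.0433, kCKpg=0.00135, KmNADn=0.409, KmNADg=40.3,
    TmaxGLCen=0.041, TmaxGLCce=0.239, TmaxGLCeg=0.147, TmaxGLCcg=0.0016,
    TmaxLACgc=0.00243, TmaxLACne=24.3, TmaxLACge=106.1, TmaxLACec=0.25,
    kHKPFKn=0.0504, kHKPFKg=0.185, kLDHmn=0.72, kLDHmg=0.071,
    PScapVn=1.66, PScapVg=0.87, Vmaxoutn=0.164, Vmaxoutg=0.064,
    Vmaxinn=0.1303, Vmaxing=5.7, kPGKn=3.97, kPGKg=135.2, kPKn=36.7, kPKg=401.7,
    JATPasesn=0.1695, JATPasesg=0.1404, kCKmn=0.00028, kCKmg=1e-5,
    TNADHn=10330.0, TNADHg=150.0, LACa=0.506,
    Nexc=1500.0, gbar=7.8e-6, dglut=2.25e-5, EAMPA=0.0,
)

ORDER = ["Na_n", "Na_g", "GLC_n", "GLC_g", "GAP_n", "GAP_g", "PEP_n", "PEP_g",
         "PYR_n", "PYR_g", "LAC_n", "LAC_g", "NADH_cyto_n", "NADH_cyto_g",
         "NADH_mito_n", "NADH_mito_g", "ATP_n", "ATP_g", "PCr_n", "PCr_g",
         "O2_n", "O2_g", "O2_c", "GLC_c", "LAC_c", "Vv", "dHb", "GLC_e",
         "LAC_e", "psi_n", "h", "n_gate", "Ca"]


def oracle_derivatives(y, f_exc=0.0, F_in=None, p=SYM):
    """State derivative by literal transcription of the printed equations."""
    s = dict(zip(ORDER, np.asarray(y, dtype=float)))
    if F_in is None:
        F_in = p["F0"]

    def ADPof(ATP):
        u = p["qAK"] ** 2 + 4 * p["qAK"] * (p["A"] / ATP - 1)
        return ATP / 2 * (-p["qAK"] + np.sqrt(u))

    def dAMPdATP(ATP):
        u = p["qAK"] ** 2 + 4 * p["qAK"] * (p["A"] / ATP - 1)
        return -1 + p["qAK"] / 2 - np.sqrt(u) / 2 + p["qAK"] * p["A"] / (ATP * np.sqrt(u))

    def T(cs, cd, Tmax, Kt):  # reversible carrier
        return Tmax * (cs / (cs + Kt) - cd / (cd + Kt))

    out = {}
    ADP = {"n": ADPof(s["ATP_n"]), "g": ADPof(s["ATP_g"])}

    # rate laws per compartment
    J = {}
    for x in ("n", "g"):
        ATP, GLC = s[f"ATP_{x}"], s[f"GLC_{x}"]
        J[f"HKPFK{x}"] = (p[f"kHKPFK{x}"] * ATP * GLC / (GLC + p["Kg"])
                          * (1 + (ATP / p["KIATP"]) ** p["nH"]) ** -1)
        J[f"PGK{x}"] = (p[f"kPGK{x}"] * s[f"GAP_{x}"] * ADP[x]
                        * (p["N"] - s[f"NADH_cyto_{x}"]) / s[f"NADH_cyto_{x}"])
        J[f"PK{x}"] = p[f"kPK{x}"] * s[f"PEP_{x}"] * ADP[x]
        J[f"LDH{x}"] = (p[f"kLDHp{x}"] * s[f"PYR_{x}"] * s[f"NADH_cyto_{x}"]
                        - p[f"kLDHm{x}"] * s[f"LAC_{x}"] * (p["N"] - s[f"NADH_cyto_{x}"]))
        J[f"min{x}"] = (p[f"Vmaxin{x}"] * s[f"PYR_{x}"] / (s[f"PYR_{x}"] + p["Kmmito"])
                        * (p["N"] - s[f"NADH_mito_{x}"])
                        / ((p["N"] - s[f"NADH_mito_{x}"]) + p[f"KmNAD{x}"]))
        J[f"mout{x}"] = (p[f"Vmaxout{x}"] * s[f"O2_{x}"] / (s[f"O2_{x}"] + p["KO2mito"])
                         * ADP[x] / (ADP[x] + p[f"KmADP{x}"])
                         * s[f"NADH_mito_{x}"] / (s[f"NADH_mito_{x}"] + p[f"KmNADH{x}"]))
        Rm = s[f"NADH_cyto_{x}"] / (p["N"] - s[f"NADH_cyto_{x}"])
        Rp = (p["N"] - s[f"NADH_mito_{x}"]) / s[f"NADH_mito_{x}"]
        J[f"sh{x}"] = (p[f"TNADH{x}"] * Rm / (Rm + p[f"Mcyto{x}"])
                       * Rp / (Rp + p[f"Mmito{x}"]))
        J[f"CK{x}"] = (p[f"kCKp{x}"] * ADP[x] * s[f"PCr_{x}"]
                       - p[f"kCKm{x}"] * s[f"ATP_{x}"] * (p["C"] - s[f"PCr_{x}"]))
        J[f"O2mc{x}"] = (p[f"PScapV{x}"]
                         * (p["KO2"] * (p["HbOP"] / s["O2_c"] - 1) ** (-1 / p["nh"])
                            - s[f"O2_{x}"]))
        psix = s["psi_n"] if x == "n" else p["psig"]
        J[f"leak{x}"] = (p[f"SmV{x}"] / p["F"] * p[f"gNa{x}"]
                         * (p["RTF"] * np.log(p["Nae"] / s[f"Na_{x}"]) - psix))
        J[f"pump{x}"] = (p[f"SmV{x}"] * p[f"kpump{x}"] * s[f"ATP_{x}"] * s[f"Na_{x}"]
                         * (1 + s[f"ATP_{x}"] / p["Kmpump"]) ** -1)

    # carriers
    J["GLCen"] = T(s["GLC_e"], s["GLC_n"], p["TmaxGLCen"], p["KtGLCen"])
    J["GLCeg"] = T(s["GLC_e"], s["GLC_g"], p["TmaxGLCeg"], p["KtGLCeg"])
    J["GLCcg"] = T(s["GLC_c"], s["GLC_g"], p["TmaxGLCcg"], p["KtGLCcg"])
    J["GLCce"] = T(s["GLC_c"], s["GLC_e"], p["TmaxGLCce"], p["KtGLCce"])
    J["LACne"] = T(s["LAC_n"], s["LAC_e"], p["TmaxLACne"], p["KtLACne"])
    J["LACge"] = T(s["LAC_g"], s["LAC_e"], p["TmaxLACge"], p["KtLACge"])
    J["LACgc"] = T(s["LAC_g"], s["LAC_c"], p["TmaxLACgc"], p["KtLACgc"])
    J["LACec"] = T(s["LAC_e"], s["LAC_c"], p["TmaxLACec"], p["KtLACec"])
    J["O2c"] = 2 * F_in / p["Vcap"] * (p["O2a"] - s["O2_c"])
    J["GLCc"] = 2 * F_in / p["Vcap"] * (p["GLCa"] - s["GLC_c"])
    J["LACc"] = 2 * F_in / p["Vcap"] * (p["LACa"] - s["LAC_c"])
    O2cbar = 2 * s["O2_c"] - p["O2a"]

    # Hodgkin-Huxley footnote kinetics
    psi = s["psi_n"]
    am = (-0.1 * (psi + 33) / (np.exp(-0.1 * (psi + 33)) - 1)
          if abs(psi + 33) > 1e-6 else 1.0)
    bm = 4 * np.exp(-(psi + 58) / 12)
    ah = 0.07 * np.exp(-(psi + 50) / 10)
    bh = 1 / (np.exp(-0.1 * (psi + 20)) + 1)
    an = (-0.01 * (psi + 34) / (np.exp(-0.1 * (psi + 34)) - 1)
          if abs(psi + 34) > 1e-6 else 0.1)
    bn = 0.125 * np.exp(-(psi + 44) / 25)
    minf, hinf, ninf = am / (am + bm), ah / (ah + bh), an / (an + bn)
    tauh, taun = 1e-3 / (ah + bh), 1e-3 / (an + bn)
    mCa = 1 / (1 + np.exp(-(psi + 20) / 9))
    ENa = p["RTF"] * np.log(p["Nae"] / s["Na_n"])
    EL = (p["gKpas"] + p["gNan"]) ** -1 * (p["gKpas"] * p["EK"] + p["gNan"] * ENa)
    IL = p["gL"] * (psi - EL)
    INa = p["gNa"] * minf ** 3 * s["h"] * (psi - ENa)
    IK = p["gK"] * s["n_gate"] ** 4 * (psi - p["EK"])
    ICa = p["gCa"] * mCa ** 2 * (psi - p["ECa"])
    ImAHP = p["gmAHP"] * s["Ca"] / (s["Ca"] + p["KD"]) * (psi - p["EK"])
    Ipump = (p["F"] * p["kpumpn"] * s["ATP_n"] * (s["Na_n"] - p["Na0"])
             * (1 + s["ATP_n"] / p["Kmpump"]) ** -1)
    gexc = p["Nexc"] * p["gbar"] * f_exc
    Isyn = gexc * (p["EAMPA"] - psi)
    Jstimn = p["SmVn"] / p["F"] * (2.0 / 3.0 * Isyn - INa)
    Jstimg = 3 * p["dglut"] * p["Nexc"] * f_exc

    # venous balloon, outflow solved from the implicit pair
    v = s["Vv"] / p["Vv0"]
    a = p["F0"] * p["tauv"] / p["Vv0"] * v ** -0.5
    Fout = (p["F0"] * v ** (1 / p["alphav"]) + a * F_in) / (1 + a)

    ren, reg = p["Ve"] / p["Vn"], p["Ve"] / p["Vg"]
    rce, rcg, rcn = p["Vcap"] / p["Ve"], p["Vcap"] / p["Vg"], p["Vcap"] / p["Vn"]

    out["Na_n"] = J["leakn"] - 3 * J["pumpn"] + Jstimn
    out["Na_g"] = J["leakg"] - 3 * J["pumpg"] + Jstimg
    out["GLC_n"] = J["GLCen"] - J["HKPFKn"]
    out["GLC_g"] = J["GLCcg"] + J["GLCeg"] - J["HKPFKg"]
    out["GAP_n"] = 2 * J["HKPFKn"] - J["PGKn"]
    out["GAP_g"] = 2 * J["HKPFKg"] - J["PGKg"]
    out["PEP_n"] = J["PGKn"] - J["PKn"]
    out["PEP_g"] = J["PGKg"] - J["PKg"]
    out["PYR_n"] = J["PKn"] - J["LDHn"] - J["minn"]
    out["PYR_g"] = J["PKg"] - J["LDHg"] - J["ming"]
    out["LAC_n"] = J["LDHn"] - J["LACne"]
    out["LAC_g"] = J["LDHg"] - J["LACge"] - J["LACgc"]
    out["NADH_cyto_n"] = (1 - p["xi"]) ** -1 * (J["PGKn"] - J["LDHn"] - J["shn"])
    out["NADH_cyto_g"] = (1 - p["xi"]) ** -1 * (J["PGKg"] - J["LDHg"] - J["shg"])
    out["NADH_mito_n"] = p["xi"] ** -1 * (4 * J["minn"] - J["moutn"] + J["shn"])
    out["NADH_mito_g"] = p["xi"] ** -1 * (4 * J["ming"] - J["moutg"] + J["shg"])
    out["ATP_n"] = ((-2 * J["HKPFKn"] + J["PGKn"] + J["PKn"] - p["JATPasesn"]
                     - J["pumpn"] + 3.6 * J["moutn"] + J["CKn"])
                    * (1 - dAMPdATP(s["ATP_n"])) ** -1)
    out["ATP_g"] = ((-2 * J["HKPFKg"] + J["PGKg"] + J["PKg"] - p["JATPasesg"]
                     - 7.0 / 4.0 * J["pumpg"] + 3.0 / 4.0 * p["Jpump0g"]
                     + 3.6 * J["moutg"] + J["CKg"])
                    * (1 - dAMPdATP(s["ATP_g"])) ** -1)
    out["PCr_n"] = -J["CKn"]
    out["PCr_g"] = -J["CKg"]
    out["O2_n"] = J["O2mcn"] - 0.6 * J["moutn"]
    out["O2_g"] = J["O2mcg"] - 0.6 * J["moutg"]
    out["O2_c"] = J["O2c"] - 1 / rcn * J["O2mcn"] - 1 / rcg * J["O2mcg"]
    out["GLC_c"] = J["GLCc"] - 1 / rce * J["GLCce"] - 1 / rcg * J["GLCcg"]
    out["LAC_c"] = J["LACc"] + 1 / rce * J["LACec"] + 1 / rcg * J["LACgc"]
    out["Vv"] = F_in - Fout
    out["dHb"] = F_in * (p["O2a"] - O2cbar) - Fout * s["dHb"] / s["Vv"]
    out["GLC_e"] = J["GLCce"] - 1 / reg * J["GLCeg"] - 1 / ren * J["GLCen"]
    out["LAC_e"] = 1 / ren * J["LACne"] + 1 / reg * J["LACge"] - J["LACec"]
    out["psi_n"] = p["Cm"] ** -1 * (-IL - INa - IK - ICa - ImAHP - Ipump + Isyn)
    out["h"] = p["phih"] / tauh * (hinf - s["h"])
    out["n_gate"] = p["phin"] / taun * (ninf - s["n_gate"])
    out["Ca"] = -p["SmVn"] / p["F"] * ICa - 1 / p["tauCa"] * (s["Ca"] - p["Ca0"])
    return np.array([out[k] for k in ORDER])
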