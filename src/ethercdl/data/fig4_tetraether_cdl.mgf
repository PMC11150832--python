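BEGIN IONS
TITLE=tetraether cardiolipin 64:0;e4 observed MS2 peak list (intensities synthetic)
PEPMASS=1298.0630
RTINSECONDS=1185.00
CHARGE=1+
155.0100 180.0000
234.9770 420.0000
255.2680 650.0000
283.2990 540.0000
297.3150 580.0000
663.5310 700.0000
691.5630 760.0000
743.4970 820.0000
771.5290 900.0000
1280.0500 1000.0000
END IONS
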