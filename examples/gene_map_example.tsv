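DNMT1	v11
GSS	vGS
GCLC	vGCS
OPLAH	v27
GPX4	vGPX
GSR	vGR
GSTA4	vGST
GSTM1	vGST
GSTM2	vGST
GSTT1	vGST
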