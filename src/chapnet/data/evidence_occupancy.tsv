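gene_id	chipseq_peaks	rnai_union	rnai_overlap
hsp-60	0	1	1
hsp-10	1	1	1
cct-1	1	1	1
cct-2	1	0	0
cct-3	0	1	1
cct-4	1	1	1
cct-5	1	0	0
cct-6	0	1	1
cct-7	1	1	1
cct-8	1	0	0
hsp-1	0	1	1
hsp-3	0	1	1
hsp-4	1	1	1
hsp-6	1	0	0
hsp-70	1	1	1
f44e5.4	1	1	1
f44e5.5	1	0	0
c12c8.1	1	0	0
f11f1.1	1	0	0
stc-1	1	1	1
t14g8.3	0	1	1
c30c11.4	0	1	1
hsp-110	1	0	0
dnj-1	1	1	1
dnj-2	0	0	0
dnj-3	1	1	1
dnj-4	0	1	1
dnj-5	0	0	0
dnj-6	1	1	1
dnj-7	1	0	0
dnj-8	0	1	1
dnj-9	1	1	1
dnj-10	1	0	0
dnj-11	0	1	1
dnj-12	1	1	1
dnj-13	1	0	0
dnj-14	0	1	1
dnj-15	1	1	1
dnj-16	1	0	0
dnj-17	0	1	1
dnj-18	1	1	1
dnj-19	1	0	0
dnj-20	0	1	1
dnj-21	1	1	1
dnj-22	1	0	0
dnj-23	0	1	1
dnj-24	1	1	1
dnj-25	1	0	0
dnj-26	0	1	1
dnj-27	1	1	1
dnj-28	1	0	0
dnj-29	0	1	1
dnj-30	1	0	0
rme-8	1	0	0
unc-23	1	1	1
t05c3.5	1	0	0
y73b6bl.12	0	1	1
f39b2.10	0	1	1
c08h9.14	0	0	0
daf-21	1	1	1
sti-1	0	0	0
c01g10.8	0	0	0
cdc-37	0	0	0
pph-5	0	0	0
fkb-6	0	0	0
unc-45	1	1	1
chn-1	0	0	0
r05f9.10	0	0	0
sgt-1	0	0	0
tah-1	0	0	0
ppt-1	0	0	0
aip-1	0	0	0
hsp-12.1	0	1	1
hsp-12.2	1	0	1
hsp-12.3	0	0	0
hsp-12.6	0	0	0
hsp-16.1	0	0	0
hsp-16.2	0	0	0
hsp-16.11	0	0	0
hsp-16.41	1	0	0
hsp-16.48	0	0	0
hsp-16.49	0	0	0
hsp-17	0	0	0
hsp-25	0	0	0
hsp-43	0	0	0
sip-1	0	1	1
f08h9.3	0	0	0
f08h9.4	0	0	0
pfd-1	0	0	0
pfd-2	0	0	0
pfd-3	0	0	0
pfd-4	0	0	0
pfd-5	0	0	0
pfd-6	0	0	0
nud-1	0	0	0
c17g10.2	0	0	0
b0035.14	0	0	0
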