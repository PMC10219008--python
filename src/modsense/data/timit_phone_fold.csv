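phone61,phone39
aa,aa
ae,ae
ah,ah
ao,aa
aw,aw
ax,ah
ax-h,ah
axr,er
ay,ay
b,b
bcl,sil
ch,ch
d,d
dcl,sil
dh,dh
dx,dx
eh,eh
el,l
em,m
en,n
eng,ng
epi,sil
er,er
ey,ey
f,f
g,g
gcl,sil
h#,sil
hh,hh
hv,hh
ih,ih
ix,ih
iy,iy
jh,jh
k,k
kcl,sil
l,l
m,m
n,n
ng,ng
nx,n
ow,ow
oy,oy
p,p
pau,sil
pcl,sil
q,
r,r
s,s
sh,sh
t,t
tcl,sil
th,th
uh,uh
uw,uw
ux,uw
v,v
w,w
y,y
z,z
zh,sh
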